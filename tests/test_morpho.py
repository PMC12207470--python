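import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popdiag import morpho
from popdiag import synthetic as syn


def brute_force_auc(scores, labels, smaller_is_positive=False):
    """Pairwise-concordance oracle with half-credit for ties."""
    s = [-x for x in scores] if smaller_is_positive else list(scores)
    pos = [x for x, y in zip(s, labels) if y]
    neg = [x for x, y in zip(s, labels) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def make_tooth_frame(rows):
    return pd.DataFrame(rows, columns=["specimen_id", "population", "sex",
                                       "tooth", "length_mm", "height_mm",
                                       "top_cusp_angle_deg", "cusp_count"])


def full_specimen(sid, pop, lengths, **kw):
    rows = []
    for tooth, length in zip(morpho.TEETH, lengths):
        rows.append([sid, pop, kw.get("sex", "F"), tooth, length,
                     kw.get("height", 5.0), kw.get("angle", 90.0),
                     kw.get("cusps", 4)])
    return rows


class TestLoadToothTable:
    def test_incomplete_specimen_excluded_per_measure(self):
        rows = full_specimen("s1", "a", [6, 7, 8, 7])
        rows += full_specimen("s2", "a", [6, 7, 8, 7])
        df = make_tooth_frame(rows)
        df.loc[(df.specimen_id == "s2") & (df.tooth == "P3"),
               "length_mm"] = np.nan
        table = morpho.load_tooth_table(df)
        sub = table.complete_subset("length_mm")
        assert set(sub["specimen_id"]) == {"s1"}
        # s2 still usable for measures it has completely
        assert set(table.complete_subset("height_mm")["specimen_id"]) == \
            {"s1", "s2"}

    def test_count_retained(self):
        rows = []
        for i in range(5):
            rows += full_specimen(f"s{i}", "a", [6, 7, 8, 7])
        df = make_tooth_frame(rows)
        df.loc[(df.specimen_id == "s4") & (df.tooth == "M1"),
               "length_mm"] = np.nan
        sub = morpho.load_tooth_table(df).complete_subset("length_mm")
        assert sub["specimen_id"].nunique() == 4

    def test_anomalous_specimen_excluded(self):
        rows = full_specimen("ok", "a", [6, 7, 8, 7])
        rows += full_specimen("bad", "a", [6, 7, 8, 7])
        df = make_tooth_frame(rows)
        df["anomaly"] = df["specimen_id"] == "bad"
        table = morpho.load_tooth_table(df)
        assert "bad" not in set(table.data["specimen_id"])
        assert table.exclusions["anomalous_specimens"] == 1

    def test_left_side_dropped(self):
        rows = full_specimen("s1", "a", [6, 7, 8, 7])
        df = make_tooth_frame(rows)
        df["side"] = "R"
        left = df.copy()
        left["side"] = "L"
        table = morpho.load_tooth_table(pd.concat([df, left]))
        assert len(table.data) == 4
        assert table.exclusions["non_right_side_rows"] == 4

    def test_unknown_tooth_error(self):
        df = make_tooth_frame([["s", "a", "F", "M2", 5, 5, 90, 4]])
        with pytest.raises(ValueError, match="tooth"):
            morpho.load_tooth_table(df)


class TestSummarize:
    def test_ratio_arithmetic(self):
        rows = full_specimen("s1", "a", [6, 7, 4.0, 3.0])  # P4=4, M1=3
        rows += full_specimen("s2", "a", [6, 7, 4.0, 4.0])
        summary = morpho.summarize(morpho.load_tooth_table(
            make_tooth_frame(rows)))
        ratios = dict(zip(summary.ratios["specimen_id"],
                          summary.ratios["m1_p4_ratio"]))
        assert ratios["s1"] == pytest.approx(0.75)
        assert ratios["s2"] == pytest.approx(1.0)
        assert summary.ratios["m1_p4_ratio"].mean() == pytest.approx(0.875)

    def test_cusp_table_shows_absent_five(self):
        rows = full_specimen("s1", "focal", [6, 7, 8, 7], cusps=4)
        rows += full_specimen("s2", "other", [6, 7, 8, 7], cusps=5)
        summary = morpho.summarize(morpho.load_tooth_table(
            make_tooth_frame(rows)))
        assert summary.cusp_counts.loc["focal", 5] == 0
        assert summary.cusp_counts.loc["other", 5] == 4

    def test_focal_preset_no_five_cusped(self):
        table, _ = syn.simulate_dentition(syn.dentition_preset(), 60, seed=2)
        summary = morpho.summarize(morpho.load_tooth_table(table))
        assert summary.cusp_counts.loc["focal", 5] == 0


class TestPermutationTest:
    def test_exact_one_sixth(self):
        res = morpho.permutation_test([1, 2], [3, 4], alternative="greater")
        assert res.exact
        assert res.p_value == pytest.approx(1 / 6)

    def test_identical_groups_p_one(self):
        res = morpho.permutation_test([5, 5], [5, 5])
        assert res.observed == 0.0
        assert res.p_value == 1.0

    def test_symmetry(self):
        a = [1.0, 2.5, 3.0]
        b = [4.0, 5.5, 2.0]
        p1 = morpho.permutation_test(a, b, alternative="greater").p_value
        p2 = morpho.permutation_test(b, a, alternative="less").p_value
        assert p1 == pytest.approx(p2)

    def test_monte_carlo_matches_exact(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 9).tolist()
        b = rng.normal(1, 1, 9).tolist()
        exact = morpho.permutation_test(a, b)  # C(18,9)=48620 > 20000? no
        # C(18,9) = 48620 -> Monte Carlo; force exact with a high limit
        exact = morpho.permutation_test(a, b, exact_limit=50_000)
        assert exact.exact
        mc = morpho.permutation_test(a, b, n_permutations=4000, seed=3)
        assert not mc.exact
        sd = math.sqrt(exact.p_value * (1 - exact.p_value) / 4000)
        assert abs(mc.p_value - exact.p_value) <= 3 * sd + 1e-3

    def test_bad_alternative(self):
        with pytest.raises(ValueError):
            morpho.permutation_test([1], [2], alternative="two-sided")

    def test_empty_group(self):
        with pytest.raises(ValueError):
            morpho.permutation_test([], [1.0])

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            a = rng.normal(size=4)
            b = rng.normal(size=5)
            p = morpho.permutation_test(a, b, seed=0).p_value
            assert 0 < p <= 1


class TestROC:
    def test_worked_example(self):
        res = morpho.roc([0.80, 0.86, 0.84, 0.95], [1, 1, 0, 0],
                         smaller_is_positive=True)
        assert res.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        res = morpho.roc([1, 2, 9, 10], [1, 1, 0, 0],
                         smaller_is_positive=True)
        assert res.auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            morpho.roc([1, 2], [1, 1])

    def test_null_distribution(self):
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(40):
            scores = rng.normal(size=200)
            labels = rng.permutation([1] * 100 + [0] * 100)
            aucs.append(morpho.roc(scores, labels).auc)
        inside = np.mean([abs(a - 0.5) < 0.12 for a in aucs])
        assert inside >= 0.95

    def test_curve_monotone(self):
        rng = np.random.default_rng(4)
        res = morpho.roc(rng.normal(size=50), rng.integers(0, 2, 50) == 1)
        assert (np.diff(res.tpr) >= 0).all()
        assert (np.diff(res.fpr) >= 0).all()
        assert res.tpr[0] == 0 and res.tpr[-1] == 1

    @given(st.integers(2, 30), st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_brute_force_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice([0.1, 0.2, 0.2, 0.3, 0.5, 0.8], size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.all() or not labels.any():
            labels[0] = 1 - labels[0]
        for orient in (False, True):
            res = morpho.roc(scores, labels == 1, smaller_is_positive=orient)
            assert res.auc == pytest.approx(
                brute_force_auc(scores, labels == 1, orient))


class TestDiagnosticCutoff:
    def test_midpoint_between_separated_groups(self):
        res = morpho.roc([0.70, 0.80, 0.90, 1.00], [1, 1, 0, 0],
                         smaller_is_positive=True)
        assert morpho.diagnostic_cutoff(res) == pytest.approx(0.85)

    def test_enumeration_oracle(self):
        # cutoff must attain the maximal Youden J over all thresholds
        rng = np.random.default_rng(11)
        scores = np.round(rng.normal(0.9, 0.1, 40), 2)
        labels = rng.integers(0, 2, 40) == 1
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        res = morpho.roc(scores, labels, smaller_is_positive=True)
        cutoff = morpho.diagnostic_cutoff(res)
        pred = scores <= cutoff
        j_at_cutoff = (pred & labels).sum() / labels.sum() - \
            (pred & ~labels).sum() / (~labels).sum()
        best = max(
            ((scores <= t) & labels).sum() / labels.sum()
            - ((scores <= t) & ~labels).sum() / (~labels).sum()
            for t in np.concatenate([scores, [0.0, 2.0]]))
        assert j_at_cutoff == pytest.approx(best)

    def test_synthetic_preset_cutoff_in_overlap(self):
        table, _ = syn.simulate_dentition(syn.dentition_preset(), 60, seed=5,
                                          size_factor_sd=0.10)
        summary = morpho.summarize(morpho.load_tooth_table(table))
        ratios = summary.ratios
        labels = (ratios["population"] == "focal").to_numpy()
        res = morpho.roc(ratios["m1_p4_ratio"].to_numpy(), labels,
                         smaller_is_positive=True)
        cutoff = morpho.diagnostic_cutoff(res)
        focal_mean = ratios.loc[labels, "m1_p4_ratio"].mean()
        other_mean = ratios.loc[~labels, "m1_p4_ratio"].mean()
        assert focal_mean < cutoff < other_mean


class TestClassifyRatio:
    def test_lectotype_positive(self):
        assert morpho.classify_ratio(0.83) == "positive"

    def test_boundary_inclusive(self):
        assert morpho.classify_ratio(0.88) == "positive"

    def test_above_cutoff_other(self):
        assert morpho.classify_ratio(0.92) == "other"

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            morpho.classify_ratio(-1.0)


class TestCrownMetrics:
    def test_flat_profile_relief_one(self):
        prof = morpho.CrownProfile(syn.simulate_crown_profile([0.0], [2.0]))
        assert morpho.crown_metrics(prof).relief == pytest.approx(1.0)

    def test_single_cusp_relief(self):
        prof = morpho.CrownProfile(syn.simulate_crown_profile([1.0], [2.0]))
        assert morpho.crown_metrics(prof).relief == pytest.approx(
            math.sqrt(2))

    def test_four_cusp_relief(self):
        prof = morpho.CrownProfile(
            syn.simulate_crown_profile([0.5] * 4, [0.5] * 4))
        assert morpho.crown_metrics(prof).relief == pytest.approx(
            math.sqrt(5), rel=1e-9)

    def test_top_cusp_angle_90(self):
        # apices at (-0.5, 0.5), (0, 1), (0.5, 0.5)
        pts = np.array([[-1, 0], [-0.5, 0.5], [-0.25, 0.25], [0, 1],
                        [0.25, 0.25], [0.5, 0.5], [1, 0]], dtype=float)
        m = morpho.crown_metrics(morpho.CrownProfile(pts))
        assert m.top_cusp_angle_deg == pytest.approx(90.0)

    def test_angle_absent_below_three_cusps(self):
        prof = morpho.CrownProfile(syn.simulate_crown_profile([1.0], [2.0]))
        assert morpho.crown_metrics(prof).top_cusp_angle_deg is None

    def test_relief_rigid_motion_and_scale_invariant(self):
        pts = syn.simulate_crown_profile([0.5, 1.0, 0.5], [1, 1, 1])
        base = morpho.crown_metrics(morpho.CrownProfile(pts)).relief
        theta = 0.7
        R = np.array([[math.cos(theta), -math.sin(theta)],
                      [math.sin(theta), math.cos(theta)]])
        moved = (pts @ R.T) * 3.7 + np.array([12.0, -4.0])
        assert morpho.crown_metrics(
            morpho.CrownProfile(moved)).relief == pytest.approx(base)

    def test_angle_monotone_in_lateral_height(self):
        angles = []
        for h in (0.9, 0.7, 0.5, 0.3):
            pts = syn.simulate_crown_profile([h, 1.0, h], [1, 1, 1])
            angles.append(morpho.crown_metrics(
                morpho.CrownProfile(pts)).top_cusp_angle_deg)
        assert all(a > b for a, b in zip(angles, angles[1:]))

    def test_degenerate_base_error(self):
        pts = np.array([[0, 0], [1, 1], [0, 0]], dtype=float)
        with pytest.raises(ValueError):
            morpho.crown_metrics(morpho.CrownProfile(pts))


class TestTongueProfile:
    def test_rectangle_all_ones_broad_tip(self):
        outline = np.array([[0, 0], [0, 1], [10, 1], [10, -1], [0, -1]],
                           dtype=float)
        prof = morpho.tongue_profile(outline)
        np.testing.assert_allclose(prof.relative_widths, 1.0, atol=1e-9)
        assert prof.broad_tip

    def test_triangle_linear_widths(self):
        outline = np.array([[0, 0], [10, 3], [10, -3]], dtype=float)
        prof = morpho.tongue_profile(outline)
        np.testing.assert_allclose(prof.relative_widths,
                                   np.linspace(0.1, 1.0, 10), atol=1e-6)
        assert not prof.broad_tip
        assert prof.relative_widths[1] == pytest.approx(0.2, abs=1e-6)

    def test_prebinned_broad_tip_rule(self):
        widths = np.array([0.5, 0.75, 0.8, 0.9, 1, 1, 1, 1, 1, 1])
        assert morpho.tongue_profile(widths).broad_tip
        widths[1] = 0.69
        assert not morpho.tongue_profile(widths).broad_tip

    def test_roundtrip_through_outline_generator(self):
        target = np.array([0.3, 0.75, 0.9, 1.0, 1.0, 1.0, 0.95, 0.9, 0.85,
                           0.8])
        outline = syn.simulate_tongue_outline(target / target.max())
        prof = morpho.tongue_profile(outline)
        np.testing.assert_allclose(prof.relative_widths, target, atol=1e-6)

    def test_self_intersecting_rejected(self):
        bad = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], dtype=float)
        with pytest.raises(ValueError, match="self-intersecting|invalid"):
            morpho.tongue_profile(bad)

    def test_wrong_bin_count(self):
        with pytest.raises(ValueError):
            morpho.tongue_profile(np.ones(9))


class TestPresetAUCOrdering:
    def test_fig_ordering(self):
        table, _ = syn.simulate_dentition(syn.dentition_preset(), 80, seed=8,
                                          size_factor_sd=0.10)
        t = morpho.load_tooth_table(table)
        summary = morpho.summarize(t)
        labels_r = (summary.ratios["population"] == "focal").to_numpy()
        auc_ratio = morpho.roc(summary.ratios["m1_p4_ratio"].to_numpy(),
                               labels_r, smaller_is_positive=True).auc
        sub = t.complete_subset("length_mm")
        aucs = {}
        for tooth in ("M1", "P4"):
            s = sub[sub["tooth"] == tooth]
            aucs[tooth] = morpho.roc(
                s["length_mm"].to_numpy(),
                (s["population"] == "focal").to_numpy(),
                smaller_is_positive=True).auc
        assert auc_ratio > aucs["M1"] > aucs["P4"]
        assert 0.4 <= aucs["P4"] <= 0.65
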