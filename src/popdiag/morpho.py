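"""Dental and tongue morphometrics.

Covers the specimen-completeness loading rule, group summaries,
one-tailed permutation tests on group means, ROC/AUC diagnostics with a
boundary-inclusive ratio classifier, crown-profile relief and top-cusp
angles, and relative tongue-width profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.stats import rankdata

TEETH = ("P2", "P3", "P4", "M1")
MEASURES = ("length_mm", "height_mm", "top_cusp_angle_deg", "cusp_count")

#: Published diagnostic cutoff for the M1/P4 length ratio.
DEFAULT_RATIO_CUTOFF = 0.88

#: Relative width at the 20% station at or above which a tongue profile
#: is flagged broad-tipped.
BROAD_TIP_THRESHOLD = 0.70

__all__ = [
    "ToothTable",
    "ToothSummary",
    "CrownProfile",
    "CrownMetrics",
    "ROCResult",
    "PermResult",
    "TongueProfile",
    "load_tooth_table",
    "summarize",
    "permutation_test",
    "roc",
    "diagnostic_cutoff",
    "classify_ratio",
    "crown_metrics",
    "tongue_profile",
    "DEFAULT_RATIO_CUTOFF",
]


# ---------------------------------------------------------------------------
# tooth tables
# ---------------------------------------------------------------------------

@dataclass
class ToothTable:
    """Long-format tooth measurements plus per-measure complete subsets."""

    data: pd.DataFrame
    exclusions: dict = field(default_factory=dict)

    def complete_subset(self, measure: str) -> pd.DataFrame:
        """Rows for specimens with ``measure`` present on all four teeth."""
        if measure not in MEASURES:
            raise KeyError(f"unknown measure {measure!r}")
        df = self.data.dropna(subset=[measure])
        counts = df.groupby("specimen_id")["tooth"].nunique()
        complete = counts[counts == len(TEETH)].index
        return df[df["specimen_id"].isin(complete)].copy()

    @property
    def populations(self) -> list:
        return sorted(self.data["population"].unique())


def load_tooth_table(path_or_frame, log=None) -> ToothTable:
    """Load a tooth CSV and apply the specimen-completeness rules.

    Keeps right-side rows only (a ``side`` column, when present, is
    filtered to 'R'; left-side rows are dropped with a note), excludes
    specimens flagged with dental anomalies, and records exclusion
    counts.  Per-measure completeness (all four of P2, P3, P4, M1
    present) is enforced lazily by :meth:`ToothTable.complete_subset`.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame.copy()
    else:
        df = pd.read_csv(path_or_frame)
    required = {"specimen_id", "population", "tooth"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tooth table missing columns: {sorted(missing)}")
    bad = set(df["tooth"]) - set(TEETH)
    if bad:
        raise ValueError(f"unknown tooth labels: {sorted(bad)}")

    exclusions = {}
    if "side" in df.columns:
        n_left = int((df["side"] != "R").sum())
        if n_left and log is not None:
            log.append(f"dropped {n_left} non-right-side rows")
        exclusions["non_right_side_rows"] = n_left
        df = df[df["side"] == "R"].drop(columns=["side"])
    if "anomaly" in df.columns:
        flagged = df.loc[df["anomaly"].fillna(False).astype(bool),
                         "specimen_id"].unique()
        exclusions["anomalous_specimens"] = len(flagged)
        if len(flagged) and log is not None:
            log.append(f"excluded {len(flagged)} specimens with anomalies")
        df = df[~df["specimen_id"].isin(flagged)].drop(columns=["anomaly"])

    for m in MEASURES:
        if m not in df.columns:
            df[m] = np.nan
    return ToothTable(data=df.reset_index(drop=True), exclusions=exclusions)


@dataclass
class ToothSummary:
    group_means: pd.DataFrame    # population x tooth means per measure
    ratios: pd.DataFrame         # per-specimen M1/P4 length ratio
    cusp_counts: pd.DataFrame    # population x cusp-count tabulation


def summarize(table: ToothTable) -> ToothSummary:
    """Population x tooth means, per-specimen M1/P4 ratios, and the
    cusp-count tabulation (always including the 5-cusp column, so its
    absence in a population is visible)."""
    rows = []
    for measure in ("length_mm", "height_mm", "top_cusp_angle_deg"):
        sub = table.complete_subset(measure)
        if sub.empty:
            continue
        g = sub.groupby(["population", "tooth"])[measure].agg(["mean", "count"])
        for (pop, tooth), r in g.iterrows():
            rows.append({"population": pop, "tooth": tooth,
                         "measure": measure, "mean": r["mean"],
                         "n": int(r["count"])})
    # height/length ratio per tooth
    sub = table.complete_subset("length_mm")
    hl = sub.dropna(subset=["height_mm"])
    if not hl.empty:
        hl = hl.assign(hl_ratio=hl["height_mm"] / hl["length_mm"])
        g = hl.groupby(["population", "tooth"])["hl_ratio"].agg(
            ["mean", "count"])
        for (pop, tooth), r in g.iterrows():
            rows.append({"population": pop, "tooth": tooth,
                         "measure": "height_length_ratio", "mean": r["mean"],
                         "n": int(r["count"])})
    group_means = pd.DataFrame(rows)

    lengths = table.complete_subset("length_mm")
    wide = lengths.pivot_table(index=["specimen_id", "population"],
                               columns="tooth", values="length_mm")
    ratios = wide.reset_index()
    ratios["m1_p4_ratio"] = ratios["M1"] / ratios["P4"]
    ratios = ratios[["specimen_id", "population", "m1_p4_ratio"]]

    cc = table.complete_subset("cusp_count")
    cusp = (cc.assign(cusp_count=cc["cusp_count"].astype(int))
            .groupby(["population", "cusp_count"]).size()
            .unstack(fill_value=0)
            .reindex(columns=[3, 4, 5], fill_value=0))
    return ToothSummary(group_means=group_means, ratios=ratios,
                        cusp_counts=cusp)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermResult:
    observed: float
    p_value: float
    alternative: str
    exact: bool
    n_permutations: int
    seed: int | None = None


def permutation_test(group_a, group_b, n_permutations: int = 10_000,
                     alternative: str = "greater",
                     seed: int = 0,
                     exact_limit: int = 20_000) -> PermResult:
    """One-tailed permutation test on the difference of group means.

    The statistic is mean(B) - mean(A).  When the number of label
    arrangements is at most ``exact_limit`` every split is enumerated
    and p = #{stat_perm as-or-more-extreme} / total, with ties counting
    as extreme; otherwise a seeded Monte Carlo estimate with the +1
    correction p = (1 + #extreme) / (1 + B) is returned.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    observed = b.mean() - a.mean()
    pooled = np.concatenate([a, b])
    n_a, n_total = len(a), len(pooled)
    total_sum = pooled.sum()
    n_arrangements = comb(n_total, n_a, exact=True)

    def stat_from_a_sum(sum_a):
        # mean(B) - mean(A) from the sum assigned to the A slots
        return (total_sum - sum_a) / (n_total - n_a) - sum_a / n_a

    tol = 1e-12
    if n_arrangements <= exact_limit:
        extreme = 0
        for idx in combinations(range(n_total), n_a):
            s = stat_from_a_sum(pooled[list(idx)].sum())
            if alternative == "greater":
                extreme += s >= observed - tol
            else:
                extreme += s <= observed + tol
        return PermResult(observed=float(observed),
                          p_value=extreme / n_arrangements,
                          alternative=alternative, exact=True,
                          n_permutations=n_arrangements)

    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        s = stat_from_a_sum(perm[:n_a].sum())
        if alternative == "greater":
            extreme += s >= observed - tol
        else:
            extreme += s <= observed + tol
    return PermResult(observed=float(observed),
                      p_value=(1 + extreme) / (1 + n_permutations),
                      alternative=alternative, exact=False,
                      n_permutations=n_permutations, seed=seed)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    thresholds: np.ndarray   # on the original score scale
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    smaller_is_positive: bool
    cutoff: float | None = None
    cutoff_rule: str = "youden"

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "tpr": self.tpr, "fpr": self.fpr})


def roc(scores, labels, smaller_is_positive: bool = False) -> ROCResult:
    """ROC curve and Mann-Whitney AUC (ties count one half).

    ``labels`` are truthy for the positive class.  With
    ``smaller_is_positive`` the orientation is applied by score
    negation, matching diagnostics where low values indicate the
    positive class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    oriented = -scores if smaller_is_positive else scores

    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = rankdata(oriented)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # curve: predict positive when oriented score >= threshold
    order = np.argsort(-oriented, kind="mergesort")
    sorted_scores = oriented[order]
    sorted_labels = labels[order]
    distinct = np.nonzero(np.diff(sorted_scores))[0]
    idx = np.concatenate([distinct, [len(sorted_scores) - 1]])
    tps = np.cumsum(sorted_labels)[idx]
    fps = np.cumsum(~sorted_labels)[idx]
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    thr_oriented = np.concatenate([[np.inf], sorted_scores[idx]])
    thresholds = -thr_oriented if smaller_is_positive else thr_oriented
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=float(auc),
                     smaller_is_positive=smaller_is_positive)


def diagnostic_cutoff(result: ROCResult) -> float:
    """Threshold maximizing Youden J = TPR - FPR.

    Ties are broken toward higher TPR; the reported cutoff is the
    midpoint between the tying threshold score and the next more
    permissive distinct score (on the original scale).
    """
    j = result.tpr - result.fpr
    best = 0
    for i in range(1, len(j)):
        if j[i] > j[best] + 1e-12 or (
                abs(j[i] - j[best]) <= 1e-12 and result.tpr[i] > result.tpr[best]):
            best = i
    thr = result.thresholds
    # the same confusion matrix holds between thr[best] and the next
    # more permissive distinct score; report their midpoint
    if best + 1 < len(thr) and np.isfinite(thr[best]):
        cutoff = float((thr[best] + thr[best + 1]) / 2.0)
    else:
        cutoff = float(thr[best])
    result.cutoff = cutoff
    return cutoff


def classify_ratio(ratio: float, cutoff: float = DEFAULT_RATIO_CUTOFF) -> str:
    """Boundary-inclusive ratio classifier: 'positive' iff ratio <= cutoff."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return "positive" if ratio <= cutoff else "other"


# ---------------------------------------------------------------------------
# crown profiles
# ---------------------------------------------------------------------------

@dataclass
class CrownProfile:
    """Ordered crown outline; first and last points are the base chord."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 \
                or len(self.points) < 3:
            raise ValueError("profile needs >= 3 (x, y) points")

    @property
    def base_chord(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))


@dataclass
class CrownMetrics:
    relief: float
    top_cusp_angle_deg: float | None
    cusp_index: float
    n_cusps: int


def _cusp_apices(points: np.ndarray) -> np.ndarray:
    """Interior vertices that are strict local maxima of height above the
    base chord."""
    p0, p1 = points[0], points[-1]
    axis = p1 - p0
    norm = np.linalg.norm(axis)
    u = axis / norm
    rel = points - p0
    height = rel[:, 0] * (-u[1]) + rel[:, 1] * u[0]
    apices = []
    for i in range(1, len(points) - 1):
        if height[i] > height[i - 1] and height[i] > height[i + 1]:
            apices.append(i)
    return np.array(apices, dtype=int)


def crown_metrics(profile: CrownProfile) -> CrownMetrics:
    """Cusp relief, top-cusp angle, and cusp index from an outline.

    relief = crown arc length / base chord length.  The top-cusp angle
    is measured at the highest apex, subtended by the apices of its two
    adjacent cusps (absent when fewer than 3 cusps).  cusp index =
    relief / (max crown height / base chord); the standardization is a
    documented placeholder for the cited crown-complexity index.
    """
    pts = profile.points
    base = profile.base_chord
    if base <= 0:
        raise ValueError("degenerate base chord")
    arc = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    relief = arc / base

    p0, p1 = pts[0], pts[-1]
    u = (p1 - p0) / base
    heights = (pts - p0) @ np.array([-u[1], u[0]])
    max_height = float(heights.max())

    apex_idx = _cusp_apices(pts)
    angle = None
    if len(apex_idx) >= 3:
        order = apex_idx[np.argsort(-heights[apex_idx], kind="mergesort")]
        top = order[0]
        pos = int(np.nonzero(apex_idx == top)[0][0])
        if 0 < pos < len(apex_idx) - 1:
            left = pts[apex_idx[pos - 1]]
            right = pts[apex_idx[pos + 1]]
            v1 = left - pts[top]
            v2 = right - pts[top]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = float(math.degrees(math.acos(np.clip(cosang, -1, 1))))
    cusp_index = relief / (max_height / base) if max_height > 0 else math.inf
    return CrownMetrics(relief=relief, top_cusp_angle_deg=angle,
                        cusp_index=cusp_index, n_cusps=len(apex_idx))


# ---------------------------------------------------------------------------
# tongue profiles
# ---------------------------------------------------------------------------

@dataclass
class TongueProfile:
    specimen_id: str
    population: str
    relative_widths: np.ndarray  # stations at 10%..100% of axis length
    broad_tip: bool

    def __post_init__(self):
        self.relative_widths = np.asarray(self.relative_widths, dtype=float)
        if len(self.relative_widths) != 10:
            raise ValueError("exactly 10 width bins required")


def tongue_profile(outline_or_widths, specimen_id: str = "",
                   population: str = "",
                   posterior_end=None) -> TongueProfile:
    """Relative tongue widths at the ten 10%-stations from the tip.

    Accepts either 10 pre-binned widths or a simple closed outline whose
    first point is the tongue tip.  The measurement axis runs from the
    tip to the posterior-body end — supplied via ``posterior_end`` or
    defaulting to the midpoint of the two outline vertices farthest from
    the tip.  Widths are measured perpendicular to that axis at the
    10%, 20%, ..., 100% stations and normalized by the maximum; the
    broad-tip flag is set when the 20% station reaches 0.70.
    """
    arr = np.asarray(outline_or_widths, dtype=float)
    if arr.ndim == 1:
        if len(arr) != 10:
            raise ValueError("pre-binned input must have 10 widths")
        widths = arr
    else:
        widths = _widths_from_outline(arr, posterior_end)
    rel = widths / widths.max()
    return TongueProfile(specimen_id=specimen_id, population=population,
                         relative_widths=rel,
                         broad_tip=bool(rel[1] >= BROAD_TIP_THRESHOLD))


def _widths_from_outline(points: np.ndarray,
                         posterior_end=None) -> np.ndarray:
    from shapely.geometry import LineString, Polygon

    poly = Polygon(points)
    if not poly.is_valid:
        raise ValueError("outline polygon is self-intersecting or invalid")
    tip = points[0]
    if posterior_end is None:
        d = np.linalg.norm(points - tip, axis=1)
        far2 = np.argsort(-d)[:2]
        posterior_end = points[far2].mean(axis=0)
    axis = np.asarray(posterior_end, dtype=float) - tip
    length = np.linalg.norm(axis)
    if length <= 0:
        raise ValueError("degenerate tip-to-posterior axis")
    u = axis / length
    v = np.array([-u[1], u[0]])
    minx, miny, maxx, maxy = poly.bounds
    span = 2 * max(maxx - minx, maxy - miny)
    widths = np.empty(10)
    for k in range(10):
        frac = min(0.1 * (k + 1), 1.0 - 1e-9)  # keep the 100% station inside
        station = tip + u * (frac * length)
        line = LineString([station - v * span, station + v * span])
        widths[k] = poly.intersection(line).length
    return widths
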