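"""Synthetic inputs with known ground truth for every pipeline stage.

None of these generators model a real demographic or developmental
process; they are deliberately simple stand-ins chosen for analytic
tractability, so downstream statistics can be checked against closed
forms.  Allele-frequency drift uses the Balding-Nichols construction
(Beta draw with mean p and variance F*p*(1-p) per branch), dentition
measures are truncated Gaussians with an optional shared per-specimen
size factor, and migration-rate tables are exact piecewise-constant
segments whose threshold crossings are known in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filters import MISSING, GenomeMask, VariantTable
from .migration import MigrationTrajectory, threshold_times

__all__ = [
    "BranchNode",
    "MigrationPulse",
    "PopModel",
    "SimConfig",
    "TruthRecord",
    "star_model",
    "simulate_genotypes",
    "simulate_migration_trajectory",
    "numeric_threshold_time",
    "ToothParams",
    "simulate_dentition",
    "dentition_preset",
    "simulate_crown_profile",
    "simulate_tongue_outline",
]

ANCESTRAL_ALLELE = "A"
DERIVED_ALLELE = "G"


# ---------------------------------------------------------------------------
# model types
# ---------------------------------------------------------------------------

@dataclass
class BranchNode:
    """Node of the population split tree.

    ``f`` is the Balding-Nichols drift coefficient of the branch leading
    into this node (ignored at the root).  Leaves carry population
    labels.
    """

    name: str | None = None
    f: float = 0.0
    children: list = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 <= self.f < 1.0:
            raise ValueError(f"branch F must be in [0, 1), got {self.f}")

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(c.depth() for c in self.children)


@dataclass
class MigrationPulse:
    donor: str
    recipient: str
    intensity: float
    time: float

    def __post_init__(self):
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("pulse intensity must be in [0, 1]")


@dataclass
class PopModel:
    """Split tree + optional admixture pulses + ancestral spectrum."""

    root: BranchNode
    outgroup: str
    pulses: list = field(default_factory=list)
    spectrum: tuple = (0.05, 0.95)

    def __post_init__(self):
        leaves = self.root.leaves()
        if len(set(leaves)) != len(leaves):
            raise ValueError("duplicate population labels in tree")
        if self.outgroup not in leaves:
            raise ValueError(f"outgroup {self.outgroup!r} is not a leaf")
        depth = self.root.depth()
        for p in self.pulses:
            for pop in (p.donor, p.recipient):
                if pop not in leaves:
                    raise ValueError(f"pulse population {pop!r} not in tree")
            if not 0.0 <= p.time <= depth:
                raise ValueError(
                    f"pulse time {p.time} outside tree depth [0, {depth}]")
        lo, hi = self.spectrum
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("spectrum bounds must satisfy 0 <= lo < hi <= 1")

    @property
    def populations(self) -> list:
        return self.root.leaves()


def star_model(drift: dict, outgroup: str, outgroup_f: float = 0.0,
               pulses=(), spectrum=(0.05, 0.95)) -> PopModel:
    """Star-shaped split tree: every population on its own branch.

    ``drift`` maps ingroup population label -> branch F.
    """
    children = [BranchNode(name=p, f=f) for p, f in drift.items()]
    if outgroup not in drift:
        children.append(BranchNode(name=outgroup, f=outgroup_f))
    return PopModel(root=BranchNode(children=children), outgroup=outgroup,
                    pulses=list(pulses), spectrum=spectrum)


@dataclass
class SimConfig:
    n_sites: int = 1000
    n_per_pop: int = 5
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 10_000_000})
    missing_rate: float = 0.0
    seed: int = 0
    #: probability that the VCF REF allele is the ancestral one; < 1 makes
    #: polarization non-trivial downstream.
    ref_is_ancestral_prob: float = 0.5
    #: relative weight of the root (shared ancestral variation) when
    #: sampling each site's mutational origin; branch weights are their
    #: drift coefficients F.  Pure drift alone cannot create alleles
    #: private to a diverged branch, so sites originating on a branch are
    #: segregating only within that branch's subtree.
    origin_root_weight: float = 1.0

    def __post_init__(self):
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if self.n_per_pop <= 0:
            raise ValueError("n_per_pop must be positive")
        if not self.chrom_lengths or any(
                length <= 0 for length in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")


@dataclass
class TruthRecord:
    """Ground truth attached to a simulated artifact."""

    ancestral: np.ndarray | None = None        # per-site ancestral allele
    pop_freqs: dict | None = None              # pop -> per-site true freq
    site_origin: np.ndarray | None = None      # 'root' or originating branch
    crossing_times: dict | None = None         # threshold -> generations
    crossing_times_numeric: dict | None = None
    pop_means: pd.DataFrame | None = None      # per-population true means


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _balding_nichols(rng, p: np.ndarray, f: float) -> np.ndarray:
    """Beta draw with mean p and variance f*p*(1-p); f=0 is a no-op."""
    if f == 0.0:
        return p.copy()
    scale = (1.0 - f) / f
    a = np.clip(p * scale, 1e-12, None)
    b = np.clip((1.0 - p) * scale, 1e-12, None)
    return rng.beta(a, b)


def _draw_into(rng, node: BranchNode, p: np.ndarray, idx: np.ndarray,
               out: dict) -> None:
    """Drift p down the subtree under ``node`` for the sites in idx."""
    if node.is_leaf:
        out[node.name][idx] = p
        return
    for child in node.children:
        _draw_into(rng, child, _balding_nichols(rng, p, child.f), idx, out)


def _collect_edges(node: BranchNode, edges: list) -> None:
    for child in node.children:
        edges.append(child)
        _collect_edges(child, edges)


def simulate_genotypes(model: PopModel, cfg: SimConfig):
    """Simulate an unpolarized :class:`VariantTable` plus its truth.

    Per site an ancestral frequency is drawn from the configured
    spectrum, drifted down each branch with a Balding-Nichols Beta draw,
    perturbed by admixture pulses, and genotypes are Binomial(2, p) per
    diploid.  The outgroup is homozygous ancestral at every site and is
    never missing.  REF/ALT orientation is randomized so the table
    exercises polarization.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_sites

    p0 = rng.uniform(model.spectrum[0], model.spectrum[1], size=n)

    # each site's derived allele originates either at the root (shared
    # ancestral variation) or on one branch (private to its subtree),
    # with branch weights equal to their drift coefficients
    edges: list = []
    _collect_edges(model.root, edges)
    edge_names = [e.name if e.name is not None else f"internal{i}"
                  for i, e in enumerate(edges)]
    edge_w = np.array(
        [0.0 if (e.is_leaf and e.name == model.outgroup) else e.f
         for e in edges])
    weights = np.concatenate([[cfg.origin_root_weight], edge_w])
    if weights.sum() <= 0:
        origin = np.zeros(n, dtype=int)
    else:
        origin = rng.choice(len(edges) + 1, size=n, p=weights / weights.sum())

    freqs = {pop: np.zeros(n) for pop in model.populations}
    root_idx = np.nonzero(origin == 0)[0]
    if len(root_idx):
        _draw_into(rng, model.root, p0[root_idx], root_idx, freqs)
    for k, edge in enumerate(edges):
        idx = np.nonzero(origin == k + 1)[0]
        if len(idx):
            _draw_into(rng, edge, p0[idx], idx, freqs)

    site_origin = np.array(
        ["root"] + edge_names, dtype=object)[origin]
    for pulse in sorted(model.pulses, key=lambda p: p.time):
        freqs[pulse.recipient] = (
            (1.0 - pulse.intensity) * freqs[pulse.recipient]
            + pulse.intensity * freqs[pulse.donor])

    pops = model.populations
    samples, populations = [], {}
    for pop in pops:
        for k in range(cfg.n_per_pop):
            s = f"{pop}_{k}"
            samples.append(s)
            populations[s] = pop

    derived = np.zeros((n, len(samples)), dtype=np.int8)
    col = 0
    for pop in pops:
        for _ in range(cfg.n_per_pop):
            if pop == model.outgroup:
                derived[:, col] = 0
            else:
                derived[:, col] = rng.binomial(2, freqs[pop])
            col += 1

    if cfg.missing_rate > 0:
        miss = rng.random(derived.shape) < cfg.missing_rate
        for i, s in enumerate(samples):
            if populations[s] == model.outgroup:
                miss[:, i] = False
        derived[miss] = MISSING

    # positions: unique uniform draws per chromosome, proportional to length
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    counts = _split_counts(n, lengths)
    chrom_col, pos_col = [], []
    for c, length, k in zip(chroms, lengths.astype(int), counts):
        if k > length:
            raise ValueError(f"more sites than bases on {c}")
        pos = _draw_unique_positions(rng, int(length), int(k))
        chrom_col.extend([c] * k)
        pos_col.extend(pos.tolist())

    # REF/ALT orientation; dosage column stores ALT copies
    ref_is_anc = rng.random(n) < cfg.ref_is_ancestral_prob
    ref = np.where(ref_is_anc, ANCESTRAL_ALLELE, DERIVED_ALLELE).astype(object)
    alt = np.where(ref_is_anc, DERIVED_ALLELE, ANCESTRAL_ALLELE).astype(object)
    dosage = derived.copy()
    flip = ~ref_is_anc
    sub = dosage[flip]
    sub[sub != MISSING] = 2 - sub[sub != MISSING]
    dosage[flip] = sub

    vt = VariantTable(
        chrom=np.array(chrom_col, dtype=object),
        pos=np.array(pos_col, dtype=np.int64),
        dosage=dosage,
        samples=samples,
        populations=populations,
        ref=ref,
        alt=alt,
    )
    truth = TruthRecord(
        ancestral=np.full(n, ANCESTRAL_ALLELE, dtype=object),
        pop_freqs={p: freqs[p] for p in pops if p != model.outgroup},
        site_origin=site_origin,
    )
    return vt, truth


def _split_counts(n: int, weights: np.ndarray) -> np.ndarray:
    """Deterministic largest-remainder split of n by weights."""
    raw = n * weights / weights.sum()
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts


def _draw_unique_positions(rng, length: int, k: int) -> np.ndarray:
    """k sorted unique 1-based positions in [1, length]."""
    draw = max(int(k * 1.2) + 16, k)
    pos = np.unique(rng.integers(1, length + 1, size=draw))
    while len(pos) < k:
        extra = rng.integers(1, length + 1, size=draw)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=k, replace=False))


def full_mask(cfg: SimConfig, role: str = "positive") -> GenomeMask:
    """Positive mask covering every simulated chromosome end to end."""
    return GenomeMask.from_intervals(
        [(c, 0, length) for c, length in cfg.chrom_lengths.items()], role=role)


# ---------------------------------------------------------------------------
# migration trajectories
# ---------------------------------------------------------------------------

def numeric_threshold_time(segments, theta: float, step: float = 1.0):
    """Fine-grid Riemann integration oracle for the M(t) crossing time.

    Independent of the closed-form code path: accumulates
    integral(2 m dt) on a grid of at most ``step`` generations and
    linearly refines within the crossing step.  Returns None when the
    threshold is never reached.
    """
    target = -math.log(1.0 - theta)
    acc = 0.0
    t = 0.0
    for duration, m in segments:
        n_steps = max(int(math.ceil(duration / step)), 1)
        h = duration / n_steps
        for _ in range(n_steps):
            inc = 2.0 * m * h
            if acc + inc >= target:
                frac = (target - acc) / inc if inc > 0 else 0.0
                return t + frac * h
            acc += inc
            t += h
    return None


def simulate_migration_trajectory(segments, pairs: int = 1, seed: int = 0,
                                  noise_sd: float = 0.0,
                                  pair_label: str = "pair",
                                  thresholds=(0.50, 0.95, 0.99)):
    """Build piecewise-constant rate tables plus truth crossing times.

    ``segments`` is a list of (duration_generations, m_per_generation).
    ``pairs`` replicate tables are produced; with ``noise_sd > 0`` each
    replicate's rates are jittered by a lognormal factor
    exp(N(0, noise_sd)).  Truth times for the noise-free trajectory are
    computed both via the closed-form inversion and the independent
    numeric integration oracle.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("at least one segment required")
    for duration, m in segments:
        if duration <= 0:
            raise ValueError("segment durations must be positive")
        if m < 0:
            raise ValueError("migration rates must be non-negative")

    rng = np.random.default_rng(seed)
    durations = np.array([d for d, _ in segments], dtype=float)
    base_m = np.array([m for _, m in segments], dtype=float)
    right = np.cumsum(durations)
    left = right - durations

    trajectories = []
    for k in range(pairs):
        m = base_m
        if noise_sd > 0:
            m = base_m * np.exp(rng.normal(0.0, noise_sd, size=len(base_m)))
        trajectories.append(MigrationTrajectory(
            left=left.copy(), right=right.copy(), m=m,
            pair=f"{pair_label}_{k}" if pairs > 1 else pair_label))

    base = MigrationTrajectory(left=left, right=right, m=base_m,
                               pair=pair_label)
    closed = threshold_times(base, thresholds=thresholds)
    truth = TruthRecord(
        crossing_times={th: (closed.times[th] if closed.reached[th] else None)
                        for th in thresholds},
        crossing_times_numeric={
            th: numeric_threshold_time(segments, th) for th in thresholds},
    )
    return trajectories, truth


def trajectory_frame(traj: MigrationTrajectory) -> pd.DataFrame:
    return pd.DataFrame({
        "left_time_boundary": traj.left,
        "right_time_boundary": traj.right,
        "m": traj.m,
    })


# ---------------------------------------------------------------------------
# dentition
# ---------------------------------------------------------------------------

TEETH = ("P2", "P3", "P4", "M1")


@dataclass
class ToothParams:
    """Per-population generative parameters for one tooth position."""

    length_mean: float
    length_sd: float
    height_mean: float
    height_sd: float
    angle_mean: float
    angle_sd: float
    cusp_probs: tuple  # P(3), P(4), P(5)

    def __post_init__(self):
        for sd in (self.length_sd, self.height_sd, self.angle_sd):
            if sd < 0:
                raise ValueError("SDs must be non-negative")
        probs = np.asarray(self.cusp_probs, dtype=float)
        if len(probs) != 3 or np.any(probs < 0) or not math.isclose(
                probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("cusp_probs must be 3 non-negative values "
                             "summing to 1")


def _truncated_normal(rng, mean, sd, size):
    """Gaussian truncated at 0 by resampling (sd=0 returns the mean)."""
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def simulate_dentition(pop_params: dict, n_per_pop: int, seed: int = 0,
                       size_factor_sd: float = 0.0):
    """Simulate a specimen x tooth measurement table.

    ``pop_params`` maps population -> {tooth -> ToothParams}.  With
    ``size_factor_sd > 0`` every specimen gets a shared multiplicative
    size factor exp(N(0, sd)) applied to lengths and heights, inducing
    the within-specimen size correlation that makes tooth-length ratios
    more diagnostic than raw lengths.
    """
    rng = np.random.default_rng(seed)
    rows = []
    mean_rows = []
    for pop, teeth in pop_params.items():
        size = (np.exp(rng.normal(0.0, size_factor_sd, n_per_pop))
                if size_factor_sd > 0 else np.ones(n_per_pop))
        sexes = rng.choice(["F", "M"], size=n_per_pop)
        for tooth in TEETH:
            tp = teeth[tooth]
            lengths = _truncated_normal(rng, tp.length_mean, tp.length_sd,
                                        n_per_pop) * size
            heights = _truncated_normal(rng, tp.height_mean, tp.height_sd,
                                        n_per_pop) * size
            angles = _truncated_normal(rng, tp.angle_mean, tp.angle_sd,
                                       n_per_pop)
            cusps = rng.choice([3, 4, 5], size=n_per_pop, p=tp.cusp_probs)
            for i in range(n_per_pop):
                rows.append({
                    "specimen_id": f"{pop}_{i}",
                    "population": pop,
                    "sex": sexes[i],
                    "tooth": tooth,
                    "length_mm": lengths[i],
                    "height_mm": heights[i],
                    "top_cusp_angle_deg": angles[i],
                    "cusp_count": int(cusps[i]),
                })
            mean_rows.append({
                "population": pop, "tooth": tooth,
                "length_mean": tp.length_mean, "height_mean": tp.height_mean,
                "angle_mean": tp.angle_mean,
                "p5": tp.cusp_probs[2],
            })
    table = pd.DataFrame(rows)
    truth = TruthRecord(pop_means=pd.DataFrame(mean_rows))
    return table, truth


def dentition_preset(populations=("focal", "refA", "refB"),
                     n_five_cusped_in_focal_zero: bool = True) -> dict:
    """Generative preset with a short-M1, tall-crowned, small-angle,
    never-five-cusped focal population against ordinary reference
    populations sharing the focal P4 length distribution."""
    base = {
        "P2": dict(length=6.8, height=5.2, angle=95.0),
        "P3": dict(length=7.6, height=5.6, angle=95.0),
        "P4": dict(length=8.0, height=5.6, angle=95.0),
        "M1": dict(length=7.6, height=5.2, angle=95.0),
    }
    focal = {
        "P2": dict(length=6.8, height=6.2, angle=72.0),
        "P3": dict(length=7.6, height=6.6, angle=72.0),
        "P4": dict(length=8.0, height=6.4, angle=72.0),
        "M1": dict(length=6.6, height=5.4, angle=72.0),
    }
    cusp_ref = (0.20, 0.65, 0.15)
    cusp_focal = (0.35, 0.65, 0.0) if n_five_cusped_in_focal_zero else cusp_ref
    params: dict = {}
    for pop in populations:
        src = focal if pop == "focal" else base
        cusp = cusp_focal if pop == "focal" else cusp_ref
        params[pop] = {
            tooth: ToothParams(
                length_mean=v["length"], length_sd=0.30,
                height_mean=v["height"], height_sd=0.30,
                angle_mean=v["angle"], angle_sd=6.0,
                cusp_probs=cusp,
            ) for tooth, v in src.items()
        }
    return params


# ---------------------------------------------------------------------------
# outlines
# ---------------------------------------------------------------------------

def simulate_crown_profile(cusp_heights, cusp_base_widths) -> np.ndarray:
    """Polyline of adjoined isoceles-triangle cusps on a flat base.

    Returns an (n, 2) point array running from (0, 0) to (L, 0) with
    L the sum of base widths.  The exact perimeter is
    sum(2 * sqrt((w/2)^2 + h^2)).
    """
    heights = list(cusp_heights)
    widths = list(cusp_base_widths)
    if not heights or len(heights) != len(widths):
        raise ValueError("need equal-length, non-empty height/width lists")
    if any(w <= 0 for w in widths):
        raise ValueError("base widths must be positive")
    if any(h < 0 for h in heights):
        raise ValueError("cusp heights must be non-negative")
    pts = [(0.0, 0.0)]
    x = 0.0
    for h, w in zip(heights, widths):
        pts.append((x + w / 2.0, float(h)))
        x += w
        pts.append((x, 0.0))
    return np.array(pts, dtype=float)


def crown_profile_perimeter(cusp_heights, cusp_base_widths) -> float:
    """Closed-form arc length of :func:`simulate_crown_profile`."""
    return float(sum(2.0 * math.hypot(w / 2.0, h)
                     for h, w in zip(cusp_heights, cusp_base_widths)))


def simulate_tongue_outline(rel_widths, length: float = 10.0) -> np.ndarray:
    """Closed polygon outline with given relative widths at the 10%..100%
    stations from the tip, symmetric about the tip-to-posterior axis."""
    rel_widths = np.asarray(rel_widths, dtype=float)
    if len(rel_widths) != 10:
        raise ValueError("need exactly 10 relative widths")
    if np.any(rel_widths <= 0) or np.any(rel_widths > 1.0):
        raise ValueError("relative widths must be in (0, 1]")
    max_w = length * 0.6  # absolute width scale; cancels on normalization
    xs = np.linspace(0.1, 1.0, 10) * length
    half = rel_widths * max_w / 2.0
    upper = [(0.0, 0.0)] + list(zip(xs, half))
    lower = list(zip(xs[::-1], -half[::-1]))
    return np.array(upper + lower, dtype=float)
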