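"""Cumulative migration probability from piecewise-constant rate tables.

Given a symmetric per-generation migration rate m(t) that is constant
within contiguous time segments, the cumulative migration probability is

    M(t) = 1 - exp(-integral_0^t 2 m(u) du)

which within a segment starting at (t_i, M_i) gives the closed form
``M(t) = 1 - (1 - M_i) * exp(-2 m_i (t - t_i))``.  Threshold crossing
times (M50/M95/M99) are obtained by exact within-segment inversion and
serve as split-time proxies once scaled to years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import read_trajectory_tsv

__all__ = [
    "MigrationTrajectory",
    "ScalingParams",
    "ThresholdReport",
    "cumulative_migration",
    "threshold_times",
    "truncate",
    "scale_to_years",
    "aggregate_pairs",
    "load_trajectory",
]

#: Boundaries below this magnitude are taken to be mutation-scaled times.
_MU_SCALE_CUTOFF = 1e-2


@dataclass
class ScalingParams:
    """Mutation rate per site per generation and generation time in years."""

    mu: float = 1.826e-8
    generation_years: float = 10.0

    def __post_init__(self):
        if self.mu <= 0 or self.generation_years <= 0:
            raise ValueError("mu and generation time must be positive")


@dataclass
class MigrationTrajectory:
    """Ordered, contiguous time segments with constant migration rate.

    Times are in generations and ``m`` is per generation; mutation-scaled
    input is converted at load time.  ``published_M`` carries an M column
    shipped with the input file, used as a cross-check diagnostic.
    """

    left: np.ndarray
    right: np.ndarray
    m: np.ndarray
    pair: str = ""
    published_M: np.ndarray | None = None

    def __post_init__(self):
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        if not (len(self.left) == len(self.right) == len(self.m)):
            raise ValueError("segment arrays must have equal length")
        if len(self.left) == 0:
            raise ValueError("trajectory needs at least one segment")
        if np.any(self.m < 0):
            raise ValueError("migration rates must be non-negative")
        if np.any(self.right <= self.left):
            raise ValueError("segment boundaries must be increasing")
        if not np.allclose(self.left[1:], self.right[:-1]):
            raise ValueError("segments must be contiguous")

    @property
    def n_segments(self) -> int:
        return len(self.m)


@dataclass
class ThresholdReport:
    """Crossing times (generations) for each requested threshold."""

    pair: str
    times: dict = field(default_factory=dict)     # theta -> generations
    reached: dict = field(default_factory=dict)   # theta -> bool

    def times_in_years(self, params: ScalingParams) -> dict:
        return {
            th: t * params.generation_years if self.reached[th] else None
            for th, t in self.times.items()
        }


def cumulative_migration(traj: MigrationTrajectory):
    """Evaluate M at segment boundaries; return (boundary times, M values,
    callable M(t), max |deviation| from any published M column).

    M values have length n_segments + 1, starting at M(0) = 0 for a
    trajectory whose first segment starts at 0 (more generally, at the
    first left boundary, before which m is taken as 0).
    """
    dt = traj.right - traj.left
    integral = np.concatenate([[0.0], np.cumsum(2.0 * traj.m * dt)])
    boundaries = np.concatenate([[traj.left[0]], traj.right])
    M = 1.0 - np.exp(-integral)

    left = traj.left
    m = traj.m

    def M_of_t(t):
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        i = np.clip(np.searchsorted(boundaries, t, side="right") - 1, 0,
                    len(m) - 1)
        tt = np.clip(t, boundaries[0], boundaries[-1])
        out = 1.0 - (1.0 - M[i]) * np.exp(-2.0 * m[i] * (tt - left[i]))
        out[t < boundaries[0]] = 0.0
        return float(out[0]) if scalar else out

    deviation = None
    if traj.published_M is not None:
        deviation = float(np.max(np.abs(traj.published_M - M[1:])))
    return boundaries, M, M_of_t, deviation


def threshold_times(traj: MigrationTrajectory,
                    thresholds=(0.50, 0.95, 0.99)) -> ThresholdReport:
    """Exact within-segment inversion of M(t) at each threshold.

    A threshold that M never reaches is flagged not-reached and gets no
    fabricated time.
    """
    for th in thresholds:
        if not 0.0 < th < 1.0:
            raise ValueError(f"threshold {th} outside (0, 1)")
    boundaries, M, _, _ = cumulative_migration(traj)
    report = ThresholdReport(pair=traj.pair)
    for th in thresholds:
        idx = np.nonzero(M[1:] >= th)[0]
        if len(idx) == 0:
            report.reached[th] = False
            report.times[th] = math.nan
            continue
        i = int(idx[0])
        t_star = traj.left[i] + math.log((1.0 - M[i]) / (1.0 - th)) / (
            2.0 * traj.m[i])
        report.reached[th] = True
        report.times[th] = float(t_star)
    return report


def truncate(traj: MigrationTrajectory, cutoff: float = 0.999) -> MigrationTrajectory:
    """Drop segments past the point where M reaches ``cutoff``.

    The crossing segment is shortened so its right boundary is the
    crossing time; an unreached cutoff leaves the trajectory unchanged.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be in (0, 1); M never reaches 1 exactly")
    report = threshold_times(traj, thresholds=(cutoff,))
    if not report.reached[cutoff]:
        return traj
    t_star = report.times[cutoff]
    keep = traj.left < t_star
    right = traj.right[keep].copy()
    right[-1] = t_star
    return replace(traj, left=traj.left[keep], right=right, m=traj.m[keep],
                   published_M=None)


def scale_to_years(t_scaled: float, params: ScalingParams | None = None) -> float:
    """Convert a mutation-scaled time to years: generations = t/mu,
    years = generations * g."""
    params = params or ScalingParams()
    if t_scaled < 0:
        raise ValueError("time must be non-negative")
    return t_scaled / params.mu * params.generation_years


def generations_to_years(t_generations: float,
                         params: ScalingParams | None = None) -> float:
    params = params or ScalingParams()
    return t_generations * params.generation_years


def load_trajectory(path, pair: str = "", units: str = "auto",
                    params: ScalingParams | None = None) -> MigrationTrajectory:
    """Load a piecewise-rate TSV, converting times to generations.

    ``units='auto'`` treats boundaries smaller than 1e-2 as
    mutation-scaled (divide by mu; m multiplied by mu so the integral of
    m dt is preserved); override with 'generations' or 'scaled'.
    """
    params = params or ScalingParams()
    df = read_trajectory_tsv(path)
    left = df["left_time_boundary"].to_numpy(float)
    right = df["right_time_boundary"].to_numpy(float)
    m = df["m"].to_numpy(float)
    if units == "auto":
        units = "scaled" if right.max() < _MU_SCALE_CUTOFF else "generations"
    if units == "scaled":
        left, right, m = left / params.mu, right / params.mu, m * params.mu
    elif units != "generations":
        raise ValueError(f"unknown units {units!r}")
    published = df["M"].to_numpy(float) if "M" in df.columns else None
    return MigrationTrajectory(left=left, right=right, m=m, pair=pair,
                               published_M=published)


def aggregate_pairs(reports, params: ScalingParams | None = None) -> pd.DataFrame:
    """Mean and sample SD (ddof=1) of crossing times per population pair.

    Takes :class:`ThresholdReport` objects whose ``pair`` labels name the
    population pair; not-reached replicates are excluded per threshold
    and counted in an ``n_excluded`` column.  Times are reported in years
    when scaling parameters are given, otherwise in generations.
    """
    rows = []
    for rep in reports:
        for th, t in rep.times.items():
            rows.append({"pair": rep.pair, "threshold": th,
                         "time": t, "reached": rep.reached[th]})
    df = pd.DataFrame(rows)
    if params is not None:
        df["time"] = df["time"] * params.generation_years
    out = []
    for (pair, th), grp in df.groupby(["pair", "threshold"], sort=True):
        ok = grp[grp["reached"]]
        out.append({
            "pair": pair,
            "threshold": th,
            "n": len(ok),
            "n_excluded": int((~grp["reached"]).sum()),
            "mean": ok["time"].mean() if len(ok) else math.nan,
            "sd": ok["time"].std(ddof=1) if len(ok) > 1 else math.nan,
            "empty": len(ok) == 0,
        })
    return pd.DataFrame(out)
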