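"""Private derived-allele patterns, fixed private alleles, and covariance
PCA over polarized genotype tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filters import MISSING, VariantTable

__all__ = [
    "PatternTable",
    "PrivateAlleleSummary",
    "PCAResult",
    "derived_patterns",
    "private_proportions",
    "fixed_private_count",
    "pca",
]


@dataclass
class PatternTable:
    """Per-site derived-allele presence bits for a set of populations."""

    populations: list
    bits: np.ndarray  # (n_sites, n_pops) bool; every row has >=1 bit set

    def unique_counts(self) -> dict:
        """Sites whose single presence bit belongs to each population."""
        single = self.bits.sum(axis=1) == 1
        out = {}
        for j, pop in enumerate(self.populations):
            out[pop] = int((single & self.bits[:, j]).sum())
        return out

    @property
    def n_sites(self) -> int:
        return len(self.bits)


@dataclass
class PrivateAlleleSummary:
    """Mean/SD of private-pattern proportions per population and
    subsample size, over seeded replicate draws."""

    table: pd.DataFrame  # population, n, mean, sd, replicates
    seed: int

    def mean(self, population: str, n: int) -> float:
        t = self.table
        row = t[(t["population"] == population) & (t["n"] == n)]
        return float(row["mean"].iloc[0])


@dataclass
class PCAResult:
    samples: list
    coordinates: np.ndarray       # (n_samples, n_pcs)
    loadings: np.ndarray          # (n_pcs, n_sites_kept)
    eigenvalues: np.ndarray       # non-increasing, >= 0
    explained_variance_ratio: np.ndarray
    n_sites_dropped: int = 0

    def frame(self) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.coordinates[:, i]
                for i in range(self.coordinates.shape[1])}
        return pd.DataFrame({"sample": self.samples, **cols})


def derived_patterns(vt: VariantTable, subsample: dict) -> PatternTable:
    """Record, per site, which populations show the derived allele.

    ``subsample`` maps population label -> individual ids to use.  Sites
    where no sampled chromosome carries the derived allele are excluded.
    """
    if not vt.polarized:
        raise ValueError("table must be polarized first")
    pops = list(subsample)
    for pop, ids in subsample.items():
        if len(ids) == 0:
            raise ValueError(f"empty subsample for population {pop!r}")
    bits = np.zeros((vt.n_sites, len(pops)), dtype=bool)
    for j, pop in enumerate(pops):
        idx = vt.sample_indices(subsample[pop])
        bits[:, j] = (vt.dosage[:, idx] >= 1).any(axis=1)
    keep = bits.any(axis=1)
    return PatternTable(populations=pops, bits=bits[keep])


def private_proportions(vt: VariantTable, n_range=range(1, 6),
                        replicates: int = 20, seed: int = 0,
                        denominator: str = "segregating") -> PrivateAlleleSummary:
    """Proportion of derived-allele patterns unique to each population.

    For each subsample size n, ``replicates`` independent uniform draws
    of n individuals per population are taken, and the unique-pattern
    proportion is computed per draw; means and SDs are over draws.

    denominator : {'segregating', 'all_sites'}
        'segregating' divides by the sites with at least one presence
        bit within the subsample (default); 'all_sites' divides by all
        sites in the table.
    """
    if not vt.polarized:
        raise ValueError("table must be polarized first")
    if denominator not in ("segregating", "all_sites"):
        raise ValueError("denominator must be 'segregating' or 'all_sites'")
    pops = vt.population_labels
    by_pop = {p: [s for s in vt.samples if vt.populations[s] == p]
              for p in pops}
    n_max = max(n_range)
    for p, ids in by_pop.items():
        if len(ids) < n_max:
            raise ValueError(
                f"population {p!r} has {len(ids)} individuals < n={n_max}")

    rng = np.random.default_rng(seed)
    rows = []
    for n in n_range:
        props = {p: [] for p in pops}
        for _ in range(replicates):
            sub = {p: list(rng.choice(by_pop[p], size=n, replace=False))
                   for p in pops}
            pt = derived_patterns(vt, sub)
            denom = pt.n_sites if denominator == "segregating" else vt.n_sites
            uniq = pt.unique_counts()
            for p in pops:
                props[p].append(uniq[p] / denom if denom else np.nan)
        for p in pops:
            arr = np.asarray(props[p], dtype=float)
            rows.append({"population": p, "n": n,
                         "mean": float(np.mean(arr)),
                         "sd": float(np.std(arr, ddof=1)) if replicates > 1
                               else 0.0,
                         "replicates": replicates})
    return PrivateAlleleSummary(table=pd.DataFrame(rows), seed=seed)


def fixed_private_count(vt: VariantTable, focal: str) -> int:
    """Sites where every called focal chromosome is derived and no
    called non-focal chromosome carries the derived allele."""
    if not vt.polarized:
        raise ValueError("table must be polarized first")
    focal_idx = vt.pop_indices(focal)
    other_idx = np.setdiff1d(np.arange(vt.n_samples), focal_idx)
    f = vt.dosage[:, focal_idx]
    o = vt.dosage[:, other_idx]
    f_called = f != MISSING
    fixed_focal = (f_called.any(axis=1)
                   & ((f == 2) | ~f_called).all(axis=1))
    absent_other = (((o == 0) | (o == MISSING)).all(axis=1))
    return int((fixed_focal & absent_other).sum())


def pca(vt: VariantTable, individuals=None, n_components: int | None = None,
        log=None) -> PCAResult:
    """Covariance PCA of the individuals x sites dosage matrix.

    Columns are mean-centered but NOT variance-normalized; missing
    dosages are mean-imputed per site before centering.  Coordinates are
    U*S from the SVD of the centered matrix; each component's sign is
    chosen so its largest-magnitude loading is positive.
    """
    ids = list(individuals) if individuals is not None else list(vt.samples)
    if len(ids) < 2:
        raise ValueError("need at least two individuals")
    if vt.n_sites < 1:
        raise ValueError("need at least one site")
    idx = vt.sample_indices(ids)
    X = vt.dosage[:, idx].T.astype(float)          # individuals x sites
    X[X == MISSING] = np.nan

    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any() and log is not None:
        for c, p in zip(vt.chrom[all_missing], vt.pos[all_missing]):
            log.drop(c, p, "pca", "all_missing_after_subset")
    X = X[:, ~all_missing]

    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    X -= X.mean(axis=0)

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(len(ids) - 1, X.shape[1])
    if n_components is not None:
        k = min(k, n_components)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]

    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1

    eig = S ** 2 / max(len(ids) - 1, 1)
    total = (S ** 2).sum()
    ratio = S ** 2 / total if total > 0 else np.zeros_like(S)
    return PCAResult(samples=ids, coordinates=U * S, loadings=Vt,
                     eigenvalues=eig, explained_variance_ratio=ratio,
                     n_sites_dropped=int(all_missing.sum()))
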