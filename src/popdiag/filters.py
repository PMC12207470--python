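"""SNP filtering chain for polarized diploid genotype tables.

The chain runs polarize -> mask -> missing/invariant -> thin -> MAF, with
each stage usable on its own.  Every dropped site can be recorded in a
:class:`FilterLog` for auditing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "VariantTable",
    "GenomeMask",
    "FilterConfig",
    "FilterLog",
    "polarize",
    "apply_masks",
    "filter_missing_invariant",
    "thin",
    "maf_filter",
    "min_derived_count",
    "run_filter_chain",
]


@dataclass
class VariantTable:
    """Bi-allelic diploid genotypes as allele dosages.

    Parameters
    ----------
    chrom, pos : ndarray
        Chromosome name and 1-based position per site; positions must be
        strictly increasing within each chromosome.
    dosage : ndarray of shape (n_sites, n_samples)
        Copies of the ALT allele (or, once polarized, of the derived
        allele) per genotype: 0, 1, 2 or ``MISSING``.
    samples : list of str
    populations : dict
        Sample id -> population label; every sample must be present.
    ref, alt : ndarray
        Allele identities per site.
    ancestral : ndarray or None
        Set by :func:`polarize`; the allele inferred ancestral per site.
    polarized : bool
        When True, ``dosage`` counts derived alleles.
    """

    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    samples: list
    populations: dict
    ref: np.ndarray
    alt: np.ndarray
    ancestral: np.ndarray | None = None
    polarized: bool = False

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        if self.dosage.shape != (len(self.pos), len(self.samples)):
            raise ValueError("dosage shape does not match sites x samples")
        missing_pops = [s for s in self.samples if s not in self.populations]
        if missing_pops:
            raise ValueError(f"samples without population label: {missing_pops}")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosages must be 0/1/2 or MISSING")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown sample id {e.args[0]!r}") from None

    def pop_indices(self, population: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples)
               if self.populations[s] == population]
        if not idx:
            raise KeyError(f"unknown population {population!r}")
        return np.array(idx, dtype=int)

    def population_of(self, sample: str) -> str:
        return self.populations[sample]

    @property
    def population_labels(self) -> list:
        seen = []
        for s in self.samples:
            p = self.populations[s]
            if p not in seen:
                seen.append(p)
        return seen

    def take_sites(self, mask_or_idx) -> "VariantTable":
        anc = self.ancestral[mask_or_idx] if self.ancestral is not None else None
        return replace(
            self,
            chrom=self.chrom[mask_or_idx],
            pos=self.pos[mask_or_idx],
            dosage=self.dosage[mask_or_idx],
            ref=self.ref[mask_or_idx],
            alt=self.alt[mask_or_idx],
            ancestral=anc,
        )

    def take_samples(self, ids) -> "VariantTable":
        idx = self.sample_indices(ids)
        return replace(
            self,
            dosage=self.dosage[:, idx],
            samples=list(ids),
            populations={s: self.populations[s] for s in ids},
        )

    def site_keys(self):
        return list(zip(self.chrom.tolist(), self.pos.tolist()))


@dataclass
class GenomeMask:
    """Set of genomic intervals, 0-based half-open, normalized on build."""

    intervals: dict = field(default_factory=dict)  # chrom -> (starts, ends)
    role: str = "positive"

    @classmethod
    def from_intervals(cls, triples, role: str = "positive") -> "GenomeMask":
        """Build from (chrom, start, end) triples; merges overlaps."""
        by_chrom: dict = {}
        for c, s, e in triples:
            s, e = int(s), int(e)
            if e <= s:
                raise ValueError(f"interval end must exceed start: {c}:{s}-{e}")
            by_chrom.setdefault(c, []).append((s, e))
        ivs = {}
        for c, pairs in by_chrom.items():
            pairs.sort()
            merged = [list(pairs[0])]
            for s, e in pairs[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts = np.array([m[0] for m in merged], dtype=np.int64)
            ends = np.array([m[1] for m in merged], dtype=np.int64)
            ivs[c] = (starts, ends)
        return cls(intervals=ivs, role=role)

    def contains(self, chrom: str, pos_1based: np.ndarray) -> np.ndarray:
        """Membership for 1-based positions (start < p <= end)."""
        pos_1based = np.asarray(pos_1based, dtype=np.int64)
        if chrom not in self.intervals:
            return np.zeros(len(pos_1based), dtype=bool)
        starts, ends = self.intervals[chrom]
        p0 = pos_1based - 1  # 0-based coordinate of the base
        i = np.searchsorted(starts, p0, side="right") - 1
        ok = i >= 0
        ok[ok] &= p0[ok] < ends[i[ok]]
        return ok

    def total_bp(self, chrom: str | None = None,
                 window: tuple | None = None) -> int:
        """Masked base pairs, optionally restricted to a half-open window."""
        chroms = [chrom] if chrom is not None else list(self.intervals)
        total = 0
        for c in chroms:
            if c not in self.intervals:
                continue
            starts, ends = self.intervals[c]
            if window is None:
                total += int((ends - starts).sum())
            else:
                lo, hi = window
                s = np.clip(starts, lo, hi)
                e = np.clip(ends, lo, hi)
                total += int(np.maximum(e - s, 0).sum())
        return total

    def triples(self):
        for c in sorted(self.intervals):
            starts, ends = self.intervals[c]
            for s, e in zip(starts.tolist(), ends.tolist()):
                yield c, s, e


@dataclass
class FilterConfig:
    max_missing: float = 0.10
    min_distance: int = 1000
    maf: float = 0.05

    def __post_init__(self):
        if not 0 <= self.max_missing <= 1:
            raise ValueError("max_missing must be in [0, 1]")
        if self.min_distance < 0:
            raise ValueError("min_distance must be >= 0")
        if not 0 <= self.maf <= 1:
            raise ValueError("maf must be in [0, 1]")


class FilterLog:
    """Per-site audit trail of why sites were dropped and at which stage."""

    def __init__(self):
        self.records = []

    def drop(self, chrom, pos, stage, reason):
        self.records.append(
            {"chrom": chrom, "pos": int(pos), "stage": stage, "reason": reason}
        )

    def drop_many(self, vt: VariantTable, mask, stage, reason):
        for c, p in zip(vt.chrom[mask], vt.pos[mask]):
            self.drop(c, p, stage, reason)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records,
                            columns=["chrom", "pos", "stage", "reason"])

    def write(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)


def polarize(vt: VariantTable, outgroup, log: FilterLog | None = None) -> VariantTable:
    """Polarize dosages against outgroup individuals.

    The ancestral allele is the allele carried homozygously by every
    called outgroup individual.  Sites with a heterozygous outgroup
    genotype, discordant outgroup homozygotes, or no called outgroup
    genotype are dropped.  Outgroup columns are removed from the result
    and dosages are recoded to derived-allele counts.
    """
    outgroup = list(outgroup)
    if not outgroup:
        raise ValueError("at least one outgroup individual required")
    og_idx = vt.sample_indices(outgroup)
    og = vt.dosage[:, og_idx]
    called = og != MISSING
    n_called = called.sum(axis=1)
    any_het = ((og == 1) & called).any(axis=1)
    has_ref = ((og == 0) & called).any(axis=1)
    has_alt = ((og == 2) & called).any(axis=1)

    keep = (n_called > 0) & ~any_het & ~(has_ref & has_alt)
    if log is not None:
        log.drop_many(vt, (n_called == 0), "polarize", "outgroup_all_missing")
        log.drop_many(vt, (n_called > 0) & any_het, "polarize",
                      "outgroup_heterozygous")
        log.drop_many(vt, (n_called > 0) & ~any_het & has_ref & has_alt,
                      "polarize", "outgroup_discordant")

    ingroup = [s for s in vt.samples if s not in set(outgroup)]
    in_idx = vt.sample_indices(ingroup)
    dosage = vt.dosage[np.ix_(keep.nonzero()[0], in_idx)].copy()

    flip = has_alt[keep]  # ancestral allele is ALT at these sites
    sub = dosage[flip]
    sub[sub != MISSING] = 2 - sub[sub != MISSING]
    dosage[flip] = sub

    ancestral = np.where(has_alt[keep], vt.alt[keep], vt.ref[keep])
    return VariantTable(
        chrom=vt.chrom[keep],
        pos=vt.pos[keep],
        dosage=dosage,
        samples=ingroup,
        populations={s: vt.populations[s] for s in ingroup},
        ref=vt.ref[keep],
        alt=vt.alt[keep],
        ancestral=ancestral,
        polarized=True,
    )


def apply_masks(vt: VariantTable, positive: GenomeMask,
                repeat: GenomeMask | None = None,
                log: FilterLog | None = None) -> VariantTable:
    """Keep sites inside the positive mask and outside the repeat mask."""
    keep = np.zeros(vt.n_sites, dtype=bool)
    for c in np.unique(vt.chrom):
        rows = (vt.chrom == c).nonzero()[0]
        pos = vt.pos[rows]
        ok = positive.contains(c, pos)
        if repeat is not None:
            ok &= ~repeat.contains(c, pos)
        keep[rows] = ok
    if log is not None:
        log.drop_many(vt, ~keep, "mask", "outside_positive_or_in_repeat")
    return vt.take_sites(keep)


def filter_missing_invariant(vt: VariantTable, cfg: FilterConfig,
                             log: FilterLog | None = None) -> VariantTable:
    """Drop sites with too much missingness or no variation.

    Missing fraction is computed over individuals and compared with a
    strict ``>`` against ``cfg.max_missing``; a site is invariant when
    all its called dosages are equal.
    """
    d = vt.dosage
    miss_frac = (d == MISSING).sum(axis=1) / vt.n_samples
    too_missing = miss_frac > cfg.max_missing

    called = d != MISSING
    lo = np.where(called, d, np.int8(100)).min(axis=1)
    hi = np.where(called, d, np.int8(-100)).max(axis=1)
    invariant = lo >= hi  # all called dosages equal (or none called)

    if log is not None:
        log.drop_many(vt, too_missing, "missing", "missing_fraction")
        log.drop_many(vt, invariant & ~too_missing, "invariant", "no_variation")
    return vt.take_sites(~(too_missing | invariant))


def thin(vt: VariantTable, cfg: FilterConfig,
         log: FilterLog | None = None) -> VariantTable:
    """Greedy left-to-right distance thinning within each chromosome.

    The first site on a chromosome is kept; each later site is kept iff
    its distance to the last *kept* site is at least ``cfg.min_distance``
    (boundary inclusive).  Deterministic, no randomness involved.
    """
    keep = np.zeros(vt.n_sites, dtype=bool)
    for c in np.unique(vt.chrom):
        rows = (vt.chrom == c).nonzero()[0]
        last = None
        for r in rows:
            p = vt.pos[r]
            if last is None or p - last >= cfg.min_distance:
                keep[r] = True
                last = p
    if log is not None:
        log.drop_many(vt, ~keep, "thin", "within_min_distance")
    return vt.take_sites(keep)


def min_derived_count(n_individuals: int, maf: float) -> int:
    """Minimum passing derived-allele count: ceil(maf * 2N) over total
    chromosomes (46 diploids at maf 0.05 -> 5)."""
    return math.ceil(maf * 2 * n_individuals)


def maf_filter(vt: VariantTable, cfg: FilterConfig,
               log: FilterLog | None = None,
               on_called: bool = False) -> VariantTable:
    """Keep sites whose derived count reaches the MAF threshold.

    By default the threshold count is ``ceil(maf * 2N)`` with N the total
    number of ingroup individuals; with ``on_called=True`` the ceiling is
    taken over called chromosomes per site instead.
    """
    d = vt.dosage
    called = d != MISSING
    derived = np.where(called, d, 0).sum(axis=1)
    if on_called:
        thresh = np.ceil(cfg.maf * 2 * called.sum(axis=1))
    else:
        thresh = min_derived_count(vt.n_samples, cfg.maf)
    keep = derived >= thresh
    if log is not None:
        log.drop_many(vt, ~keep, "maf", "below_min_derived_count")
    return vt.take_sites(keep)


def run_filter_chain(vt: VariantTable, outgroup, positive: GenomeMask,
                     repeat: GenomeMask | None = None,
                     cfg: FilterConfig | None = None,
                     log: FilterLog | None = None) -> VariantTable:
    """polarize -> mask -> missing/invariant -> thin -> MAF."""
    cfg = cfg or FilterConfig()
    vt = polarize(vt, outgroup, log)
    vt = apply_masks(vt, positive, repeat, log)
    vt = filter_missing_invariant(vt, cfg, log)
    vt = thin(vt, cfg, log)
    vt = maf_filter(vt, cfg, log)
    return vt
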