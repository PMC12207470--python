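"""Windowed genome trees: tiling, haploidization, invariant accounting,
a neighbor-joining stand-in for external ML inference, and monophyly /
clade-support summaries over tree sets.

The bundled NJ inference is a deliberately simple, deterministic
substitute for external maximum-likelihood trees, which remain
first-class input (newick, one tree per line).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .filters import MISSING, GenomeMask, VariantTable

__all__ = [
    "WindowSpec",
    "Window",
    "WindowAlignment",
    "MonophylySummary",
    "tile_windows",
    "haploidize",
    "count_invariants",
    "nj_tree",
    "infer_tree_nj",
    "clade_support",
]


@dataclass
class WindowSpec:
    length: int = 1_000_000
    gap: int = 500_000
    offset: int = 0

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("window length must be positive")
        if self.gap < 0 or self.offset < 0:
            raise ValueError("gap and offset must be non-negative")


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 0-based half-open
    end: int


@dataclass
class WindowAlignment:
    """Haploid 0/1 alignment over the variable sites of one window."""

    window: Window
    taxa: list
    matrix: np.ndarray          # (n_taxa, n_variable) uint8
    n_turned_invariant: int     # sites monomorphic after allele sampling
    seed: int | None = None

    @property
    def n_variable(self) -> int:
        return self.matrix.shape[1]

    def sequences(self, alleles=("A", "G")) -> dict:
        """FASTA-ready sequences; 0 -> ancestral letter, 1 -> derived."""
        return {
            t: "".join(alleles[v] for v in self.matrix[i])
            for i, t in enumerate(self.taxa)
        }


@dataclass
class MonophylySummary:
    n_trees: int
    n_focal_monophyletic: int
    clade_fractions: dict = field(default_factory=dict)
    n_skipped: int = 0
    skipped_reasons: list = field(default_factory=list)

    @property
    def focal_fraction(self) -> float:
        return self.n_focal_monophyletic / self.n_trees

    def majority_clades(self) -> dict:
        """Clades supported by a strict majority (fraction > 0.5)."""
        return {c: f for c, f in self.clade_fractions.items() if f > 0.5}


def tile_windows(chrom_lengths: dict, spec: WindowSpec | None = None) -> list:
    """Fixed windows from the chromosome start, separated by gaps;
    trailing partial windows are discarded."""
    spec = spec or WindowSpec()
    windows = []
    step = spec.length + spec.gap
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome length must be positive: {chrom}")
        start = spec.offset
        while start + spec.length <= length:
            windows.append(Window(chrom=chrom, start=start,
                                  end=start + spec.length))
            start += step
    return windows


def haploidize(vt: VariantTable, window: Window | None = None,
               seed: int | None = 0) -> WindowAlignment:
    """One haploid allele per individual per site.

    Sites with any missing genotype are excluded entirely.  Homozygotes
    emit their allele; heterozygotes emit one allele uniformly at random
    (seeded).  Sites where every emitted allele coincides are moved to
    the sampling-turned-invariant tally and excluded from the variable
    matrix.
    """
    if not vt.polarized:
        raise ValueError("table must be polarized first")
    if window is not None:
        in_win = (vt.chrom == window.chrom) & (vt.pos > window.start) \
            & (vt.pos <= window.end)
        vt = vt.take_sites(in_win)
    else:
        window = Window(chrom="*", start=0,
                        end=int(vt.pos.max()) if vt.n_sites else 0)

    rng = np.random.default_rng(seed)
    d = vt.dosage
    complete = (d != MISSING).all(axis=1)
    d = d[complete]

    # 0 -> 0, 2 -> 1, 1 -> coin flip
    hap = (d == 2).astype(np.uint8)
    het = d == 1
    hap[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.uint8)

    mono = (hap == hap[:, :1]).all(axis=1) if hap.shape[0] else \
        np.zeros(0, dtype=bool)
    n_turned = int(mono.sum())
    return WindowAlignment(window=window, taxa=list(vt.samples),
                           matrix=hap[~mono].T.copy(),
                           n_turned_invariant=n_turned, seed=seed)


def count_invariants(window: Window, positive: GenomeMask,
                     alignment: WindowAlignment) -> int:
    """Invariant-site count for a window: positively-masked bp minus the
    variable sites remaining after allele sampling (so sites turned
    invariant by sampling augment the invariant tally)."""
    masked_bp = positive.total_bp(window.chrom, (window.start, window.end))
    invariant = masked_bp - alignment.n_variable
    if invariant < 0:
        raise ValueError(
            f"mask inconsistent with variants in {window}: "
            f"{alignment.n_variable} variable sites but only "
            f"{masked_bp} masked bp")
    return invariant


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _pair_order_key(labels, i, j):
    a, b = sorted((labels[i], labels[j]))
    return (a, b)


def nj_tree(dist: np.ndarray, labels) -> str:
    """Neighbor joining on a distance matrix; returns an unrooted newick.

    Deterministic: Q-ties are broken by the lexicographic order of the
    smallest leaf label under each candidate node.  Negative branch
    lengths are clamped to 0.
    """
    dist = np.asarray(dist, dtype=float)
    labels = list(labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 taxa for NJ")
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")

    # active nodes: newick fragment + sort key (smallest contained leaf)
    nodes = [(lbl, lbl) for lbl in labels]
    D = dist.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i, j in itertools.combinations(range(m), 2):
            q = (m - 2) * D[i, j] - r[i] - r[j]
            key = tuple(sorted((nodes[i][1], nodes[j][1])))
            if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[3]):
                best = (q, i, j, key)
        _, i, j, _ = best
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new_frag = (f"({nodes[i][0]}:{li:.10g},{nodes[j][0]}:{lj:.10g})")
        new_key = min(nodes[i][1], nodes[j][1])

        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = d_new[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [(new_frag, new_key)]

    # three remaining nodes joined at an unresolved center
    (a, b, c) = range(3)
    la = max((D[a, b] + D[a, c] - D[b, c]) / 2.0, 0.0)
    lb = max((D[a, b] + D[b, c] - D[a, c]) / 2.0, 0.0)
    lc = max((D[a, c] + D[b, c] - D[a, b]) / 2.0, 0.0)
    order = sorted(range(3), key=lambda k: nodes[k][1])
    lens = {a: la, b: lb, c: lc}
    parts = ",".join(f"{nodes[k][0]}:{lens[k]:.10g}" for k in order)
    return f"({parts});"


def infer_tree_nj(alignment: WindowAlignment,
                  n_invariant: int = 0) -> str:
    """NJ on normalized Hamming distances diluted by invariant sites.

    distance(i, j) = mismatches / (n_variable + n_invariant); a crude
    stand-in for ascertainment-corrected ML inference.
    """
    if len(alignment.taxa) < 3:
        raise ValueError("need at least 3 sequences")
    X = alignment.matrix.astype(np.int16)
    denom = alignment.n_variable + n_invariant
    if denom <= 0:
        raise ValueError("no sites to compute distances over")
    diff = (X[:, None, :] != X[None, :, :]).sum(axis=2)
    D = diff / denom
    return nj_tree(D, alignment.taxa)


# ---------------------------------------------------------------------------
# clade support
# ---------------------------------------------------------------------------

def _read_trees(trees):
    """Accept a TreeList, list of newick strings, or a path."""
    if isinstance(trees, dendropy.TreeList):
        return trees
    tns = dendropy.TaxonNamespace()
    if isinstance(trees, (list, tuple)):
        data = "\n".join(trees)
        return dendropy.TreeList.get(data=data, schema="newick",
                                     taxon_namespace=tns,
                                     preserve_underscores=True)
    return dendropy.TreeList.get(path=str(trees), schema="newick",
                                 taxon_namespace=tns,
                                 preserve_underscores=True)


def _leaf_labels(node):
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def clade_support(trees, focal, outgroup=(), sample_size: int | None = 500,
                  seed: int = 0) -> MonophylySummary:
    """Fraction of trees in which the focal taxa form a clade.

    Trees are optionally subsampled uniformly without replacement (when
    more than ``sample_size`` are supplied), rooted on the edge above
    the outgroup's most recent common ancestor, and the outgroup is
    pruned before testing monophyly.  Trees missing a focal taxon or
    with a non-monophyletic outgroup are skipped with a logged reason.
    Per-clade frequencies over the scored trees are also returned.
    """
    focal = frozenset(focal)
    outgroup = frozenset(outgroup)
    if focal & outgroup:
        raise ValueError("focal and outgroup taxa overlap")
    tree_list = _read_trees(trees)

    indices = np.arange(len(tree_list))
    if sample_size is not None and sample_size < len(tree_list):
        rng = np.random.default_rng(seed)
        indices = np.sort(rng.choice(indices, size=sample_size,
                                     replace=False))

    n_scored = 0
    n_mono = 0
    clade_counts: dict = {}
    skipped = []
    for idx in indices:
        tree = tree_list[int(idx)].clone(depth=1)
        labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
        if not focal <= labels:
            skipped.append((int(idx), "focal_taxon_missing"))
            continue
        if outgroup:
            if not outgroup <= labels:
                skipped.append((int(idx), "outgroup_taxon_missing"))
                continue
            ok = _root_and_prune_outgroup(tree, outgroup)
            if not ok:
                skipped.append((int(idx), "outgroup_not_monophyletic"))
                continue
        n_scored += 1
        clades = set()
        for node in tree.preorder_internal_node_iter():
            leaves = _leaf_labels(node)
            if 1 < len(leaves) < len(labels - outgroup):
                clades.add(leaves)
        if focal in clades or len(focal) == 1:
            n_mono += 1
        for c in clades:
            clade_counts[c] = clade_counts.get(c, 0) + 1

    if n_scored == 0:
        raise ValueError("no usable trees")
    fractions = {c: cnt / n_scored for c, cnt in clade_counts.items()}
    return MonophylySummary(n_trees=n_scored, n_focal_monophyletic=n_mono,
                            clade_fractions=fractions,
                            n_skipped=len(skipped), skipped_reasons=skipped)


def _root_and_prune_outgroup(tree: dendropy.Tree, outgroup) -> bool:
    """Root on the edge above the outgroup MRCA, then prune the outgroup.

    Returns False (tree unusable) when the outgroup is not monophyletic
    in the rooted tree.
    """
    taxa = [t for t in tree.taxon_namespace if t.label in outgroup]
    ingroup_leaf = next(lf for lf in tree.leaf_node_iter()
                        if lf.taxon.label not in outgroup)
    # ensure the outgroup MRCA is well-defined: root away from it first
    tree.reroot_at_edge(ingroup_leaf.edge, update_bipartitions=True)
    mrca = tree.mrca(taxa=taxa)
    if _leaf_labels(mrca) != frozenset(outgroup):
        return False
    tree.reroot_at_edge(mrca.edge, update_bipartitions=False)
    tree.prune_taxa(taxa, suppress_unifurcations=True)
    return True


def bipartitions(tree_or_newick, restrict_to=None) -> set:
    """Non-trivial leaf-set bipartitions, as frozensets of the smaller
    side's labels (unrooted comparison helper)."""
    if isinstance(tree_or_newick, str):
        tree = dendropy.Tree.get(data=tree_or_newick, schema="newick",
                                 preserve_underscores=True)
    else:
        tree = tree_or_newick
    all_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if restrict_to is not None:
        all_labels &= set(restrict_to)
    splits = set()
    for node in tree.preorder_internal_node_iter():
        side = _leaf_labels(node) & all_labels
        other = frozenset(all_labels - side)
        side = frozenset(side)
        if len(side) < 2 or len(other) < 2:
            continue
        splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits
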