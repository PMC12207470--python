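"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinate conventions are centralized here: VCF positions are 1-based,
BED intervals 0-based half-open.  All writers emit uncompressed text.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .filters import MISSING, FilterLog, GenomeMask, VariantTable

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(vt: VariantTable, path) -> None:
    """Write a minimal VCF 4.2 with GT-only genotypes."""
    chroms = []
    for c in vt.chrom:
        if c not in chroms:
            chroms.append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            length = int(vt.pos[vt.chrom == c].max()) + 1000 if vt.n_sites else 1000
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(vt.samples) + "\n")
        for i in range(vt.n_sites):
            gts = "\t".join(_GT_STRINGS[int(d)] for d in vt.dosage[i])
            fh.write(f"{vt.chrom[i]}\t{vt.pos[i]}\t.\t{vt.ref[i]}\t{vt.alt[i]}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path, populations: dict, log: FilterLog | None = None) -> VariantTable:
    """Read a VCF into an (unpolarized) :class:`VariantTable`.

    Multi-allelic and non-SNP records are dropped (with a log entry when
    a log is supplied).  ``populations`` maps sample id -> label and must
    cover every sample in the file.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chrom, pos, ref, alt, rows = [], [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            if log is not None:
                log.drop(v.CHROM, v.POS, "load", "multiallelic_or_indel")
            continue
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        gt = v.gt_types.astype(np.int8)  # 0/1/2, 3 = unknown
        gt[gt == 3] = MISSING
        rows.append(gt)
    dosage = (np.vstack(rows) if rows
              else np.zeros((0, len(samples)), dtype=np.int8))
    return VariantTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        dosage=dosage,
        samples=samples,
        populations={s: populations[s] for s in samples},
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
    )


def write_popmap(populations: dict, path) -> None:
    pd.DataFrame(
        {"sample": list(populations), "population": list(populations.values())}
    ).to_csv(path, sep="\t", index=False)


def read_popmap(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample"], df["population"]))


def write_bed(mask: GenomeMask, path) -> None:
    with open(path, "w") as fh:
        for c, s, e in mask.triples():
            fh.write(f"{c}\t{s}\t{e}\n")


def read_bed(path, role: str = "positive") -> GenomeMask:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str})
    return GenomeMask.from_intervals(
        df.itertuples(index=False, name=None), role=role)


def write_trajectory_tsv(df: pd.DataFrame, path) -> None:
    """Write a piecewise migration table (columns at least
    left_time_boundary, right_time_boundary, m)."""
    df.to_csv(path, sep="\t", index=False)


def read_trajectory_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"left_time_boundary", "right_time_boundary", "m"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory TSV missing columns: {sorted(missing)}")
    return df


def write_fasta(sequences: dict, path, width: int = 70) -> None:
    """Write name -> sequence-string mapping as FASTA."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
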