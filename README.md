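# popdiag

Genomic and morphometric distinctness diagnostics for structured
populations: private derived-allele statistics, windowed genome trees
with monophyly summaries, cumulative-migration split-time proxies, and
dental/tongue morphometric classifiers — plus seeded synthetic-data
generators so the whole pipeline is testable offline.

## Modules

| module | what it does |
|---|---|
| `popdiag.synthetic` | Seeded generators for every input the pipeline consumes (VCF genotypes via a Balding–Nichols split-tree model with branch-origin mutations, piecewise migration-rate TSVs, tooth-measure CSVs, crown/tongue outline CSVs), each with ground-truth records. All generative choices are simple, analytically tractable stand-ins — none models a real biological process. |
| `popdiag.filters` | SNP filter chain: outgroup polarization → positive/repeat mask intersection → missingness/invariant exclusion → 1-kbp distance thinning → derived-count MAF filter, with a per-site audit log. |
| `popdiag.popgen` | Derived-allele presence patterns, private-pattern proportions over subsample sizes (seeded replicate draws), fixed private-allele counts, and covariance PCA (mean-centered, not variance-normalized, mean-imputed missing dosages). |
| `popdiag.windows` | Window tiling (1 Mbp windows / 0.5 Mbp gaps by default), haploidization with seeded heterozygote sampling, invariant-site accounting against the positive mask, a deterministic neighbor-joining stand-in for external ML trees, and monophyly/clade support over newick tree sets (rooted on an outgroup that is then pruned). |
| `popdiag.migration` | Cumulative migration probability M(t) = 1 − exp(−∫2m dt) over piecewise-constant rate tables, exact M50/M95/M99 threshold inversion, 0.999 truncation, mutation-rate/generation-time scaling to years, and replicate-pair mean/SD aggregation. |
| `popdiag.morpho` | Tooth-table loading with specimen-completeness rules, group summaries, one-tailed permutation tests (exact enumeration or seeded Monte Carlo), ROC/AUC with a Youden-J cutoff, the boundary-inclusive M1/P4 ratio classifier (default cutoff 0.88), crown-profile relief/top-cusp angle/cusp index, and ten-bin relative tongue-width profiles. |

## CLI

One entry point, `popdiag`, with task groups:

```bash
# generate synthetic inputs (VCF + popmap + mask, trajectory TSVs, tooth CSV, outlines)
popdiag simulate genotypes --seed 1 --out sim/
popdiag simulate trajectory --seed 1 --out traj/
popdiag simulate dentition --seed 1 --out teeth/
popdiag simulate crown --heights 0.5,1,0.5 --widths 1,1,1 --out crown.csv
popdiag simulate tongue --widths 0.5,0.75,0.9,1,1,1,1,1,1,1 --out tongue.csv

# SNP filter chain
popdiag filter --vcf sim/genotypes.vcf --popmap sim/popmap.tsv \
    --positive-bed sim/positive_mask.bed --outgroup outgroup \
    --max-missing 0.10 --min-dist 1000 --maf 0.05 \
    --out filtered.vcf --log filter_log.tsv

# population-genetic statistics
popdiag private-alleles --vcf sim/genotypes.vcf --popmap sim/popmap.tsv \
    --outgroup outgroup --n-range 1:5 --replicates 20 --seed 0 --out priv.tsv
popdiag fixed-private --vcf sim/genotypes.vcf --popmap sim/popmap.tsv \
    --outgroup outgroup --focal focal
popdiag pca --vcf sim/genotypes.vcf --popmap sim/popmap.tsv \
    --outgroup outgroup --out pca.tsv

# windowed genome trees and monophyly support
popdiag windows tile --chrom-lengths chr1=4500000 --out windows.bed
popdiag windows nj --vcf sim/genotypes.vcf --popmap sim/popmap.tsv \
    --outgroup outgroup --positive-bed sim/positive_mask.bed --out trees.nwk
popdiag windows support --trees trees.nwk --focal focal_0,focal_1 \
    --sample 500 --seed 0

# split-time proxies from migration-rate tables
popdiag migration thresholds traj/trajectory_*.tsv \
    --mu 1.826e-8 --gen-time 10 --out thresholds.tsv
popdiag migration truncate traj/trajectory_pair.tsv --cutoff 0.999 --out t.tsv
popdiag migration aggregate traj/trajectory_*.tsv --out table.tsv

# morphometrics
popdiag teeth summarize teeth/teeth.csv --out means.tsv
popdiag teeth roc teeth/teeth.csv --positive-population focal
popdiag teeth permtest teeth/teeth.csv --group-a focal --group-b refA \
    --tooth M1 --measure length_mm --permutations 10000 --seed 0
popdiag teeth classify --ratio 0.83          # -> positive (<= 0.88)
popdiag teeth crown crown.csv
popdiag teeth tongue tongue.csv
```

External trees are first-class input to `windows support` (newick, one
tree per line); the bundled NJ inference is a deterministic stand-in for
out-of-scope maximum-likelihood inference.

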