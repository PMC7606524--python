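# ncembryo

Linking non-coding RNAs to spatiotemporal gene expression in single-cell
embryo transcriptomes.

During *C. elegans* embryogenesis, cells differentiate under tight
spatiotemporal control of gene expression, and full-length single-cell
RNA-seq captures not only protein-coding mRNAs but eight classes of
polyadenylation-compatible ncRNAs (antisense, lincRNA, rRNA, snoRNA,
pseudogene, snRNA, tRNA and ncRNAs of unknown type). `ncembryo` is a tested
re-implementation of the analysis pipeline that asks whether those ncRNAs
track — and could regulate — developmental gene expression. It is aimed at
computational biologists who want each stage of that analysis as a reusable,
separately testable function, driven by a synthetic-embryo generator in
which every claimed signal is planted and therefore recoverable.

## What the pipeline computes

- **Detection accounting** — TPM quantification
  (`TPM_g = 10^6 (c_g/ℓ_g) / Σ_j (c_j/ℓ_j)` from counts `c` and gene
  lengths `ℓ`), the strict `TPM > 1` detection rule, and a per-biotype
  summary table with detect ratios in percent.
- **Embryo-time staging** — Pearson correlation of each cell's
  `log2(TPM+1)` profile over time-variable genes with each column of a
  bulk time course; loess (span 0.75) of R versus time; the curve maximum
  is the cell's embryo time, binned into ten intervals from <150 to
  >760 min.
- **Feature-subset clustering** — log-normalization
  (`ln(1 + 10^4 c_g / Σ c)`), per-gene standardization, PCA (top 20 PCs),
  shared-nearest-neighbor graph (k = 20) with Leiden modularity clustering
  at resolution 1.0 — run on all genes, coding genes only, or ncRNAs only,
  with contingency/adjusted-Rand comparison of the partitions.
- **Marker detection** — per cluster, genes expressed in ≥ 75 % of member
  cells with natural-log fold change > 0.25 (fold change > e^0.25),
  two-sided Wilcoxon rank-sum p with Bonferroni adjustment, top 10 by fold
  change.
- **Co-expression screen** — all (ncRNA, coding) Pearson correlations on
  `log2(TPM+1)`; pairs kept at |R| > 0.6 and p < 1e−5; an ncRNA becomes a
  *hub* when it has ≥ 4 positively or ≥ 4 negatively co-expressed coding
  partners (signs never pooled) — guilt by association.
- **Temporal trends** — z-scored `log2(TPM+1)` loess-smoothed (span 0.5)
  along embryo time; genes whose fitted curve is pointwise non-increasing
  over 270–830 min with ≥ 0.5 scaled units of total decline.
- **Synthetic embryo generator** — ~1031 cells, six cell types, planted
  markers, planted positive/negative ncRNA hubs, smooth time-variable
  profiles, monotone decliners, a noise-free bulk reference and a cell type
  whose identity is carried *only* by ncRNA composition; negative-binomial
  counts with logistic dropout; fully determined by one seed.

## Worked example

```sh
python examples/embryo_time_staging.py
```

prints (abridged):

```
 cell_id  embryo_time_min  assigned_bulk_timepoint    max_R interval  low_confidence
cell0000            800.0                    800.0 0.911181     >760           False
cell0001            291.0                    300.0 0.831619  270–330           False
...
Spearman rho(true, estimated) over 400 cells: 0.995
median |error|: 24.8 min
```

Each synthetic cell's hidden developmental age is recovered to ~25 min by
correlation against the bulk reference; rho = 0.995 says the ordering of
cells along developmental time is essentially exact. Likewise

```sh
python examples/coexpression_hubs.py
```

```
48 retained pairs; 8 passing hubs
             ncrna_id  n_pos_partners  n_neg_partners
   nc_pseudogene_0010               0               6
         nc_rRNA_0001               6               0
...
precision 1.00, recall 1.00 against the 8 planted hubs
```

the screen recovers exactly the eight planted regulatory ncRNAs — six with
positive and two with negative partner sets — and nothing else. The other
example scripts (`detection_accounting.py`, `feature_set_clustering.py`,
`temporal_trends.py`) cover the remaining stages; each prints what its
numbers mean.

A thin CLI wraps the same pipeline for shell use:

```sh
ncembryo run-all --seed 7 --outdir out/
```

## Layout

- `src/ncembryo/` — the library (`io`, `simulate`, `profile`, `staging`,
  `clustering`, `markers`, `coexpression`, `trends`, `pipeline`, `cli`,
  `benchmarks`)
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, parameter choices and limitations
- `tests/` — pytest suite including the acceptance checks
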