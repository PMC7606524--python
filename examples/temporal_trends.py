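"""Detecting genes whose expression declines monotonically with embryo time.

Twenty planted genes (16 coding, 4 ncRNA) decay smoothly over 270-830 min.
Cells are staged first; each gene's z-scored log2(TPM+1) is then loess-
smoothed along estimated time and flagged when the fitted curve is
pointwise non-increasing with a total decline of at least 0.5 scaled units.
"""

import numpy as np

import ncembryo as nc

counts, tpm, genes, bulk, truth = nc.simulate(nc.SimulationConfig(n_cells=600, seed=23))
log2tpm = nc.log2_tpm(tpm)
staged = np.array([r.embryo_time_min for r in nc.stage_cells(log2tpm, bulk)])
fits = nc.detect_decreasing(log2tpm, staged)

flagged = {f.gene_id for f in fits}
planted = set(truth.trend_genes)
print(f"{len(fits)} genes flagged as continuously decreasing")
print(f"all {len(planted)} planted decliners recovered: {planted <= flagged}")
for fit in sorted(fits, key=lambda f: -f.total_decline)[:5]:
    print(f"  {fit.gene_id}: decline {fit.total_decline:.2f} scaled units")

shuffled = np.random.default_rng(0).permutation(staged)
null = nc.detect_decreasing(log2tpm, shuffled)
print(f"\ntime-shuffled control: {len(null)} of {log2tpm.n_genes} genes flagged "
      f"({100 * len(null) / log2tpm.n_genes:.2f}%)")
print(
    "\nGenes declining from the 270-min mark onward are candidates for\n"
    "early-embryo programs that switch off as differentiation proceeds;\n"
    "the shuffled control shows the detector's false-flag rate is tiny."
)
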