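"""Clustering the same cells on coding-only vs ncRNA-only features.

The generator plants one cell type (muscle) whose identity lives entirely
in ncRNA composition: on coding genes each muscle cell mimics another
differentiated type.  ncRNA-only clustering pulls these cells into one
cluster; coding-only clustering scatters them.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

import ncembryo as nc

counts, tpm, genes, bulk, truth = nc.simulate(nc.SimulationConfig(n_cells=400, seed=5))
config = nc.ClusteringConfig(seed=5)
labels_ncrna = nc.run_feature_set_clustering(counts, genes, "ncrna", config)
labels_coding = nc.run_feature_set_clustering(counts, genes, "coding", config)

muscle = np.array([t == "muscle" for t in truth.cell_types])
best = max(np.unique(labels_ncrna), key=lambda k: muscle[labels_ncrna == k].sum())
print(f"{muscle.sum()} muscle cells among {len(muscle)}")
print(f"ncRNA-only cluster {best}: "
      f"{100 * muscle[labels_ncrna == best].mean():.0f}% muscle, "
      f"captures {100 * (labels_ncrna[muscle] == best).mean():.0f}% of muscle cells")
print(f"coding-only clustering spreads muscle over "
      f"{len(np.unique(labels_coding[muscle]))} clusters")
print(f"ARI vs muscle indicator — ncRNA features: "
      f"{adjusted_rand_score(labels_ncrna, muscle):.3f}, "
      f"coding features: {adjusted_rand_score(labels_coding, muscle):.3f}")
print(
    "\nThe higher ncRNA-feature ARI shows a cell type that only ncRNA\n"
    "expression can resolve — ncRNA-based clustering complements the\n"
    "standard coding-gene clustering."
)
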