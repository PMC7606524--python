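import numpy as np
import pytest

import ncembryo as nc


@pytest.fixture(scope="session")
def small_sim():
    """A small default-condition simulation shared across test modules."""
    cfg = nc.SimulationConfig(n_cells=300, seed=7)
    counts, tpm, genes, bulk, truth = nc.simulate(cfg)
    return {
        "config": cfg,
        "counts": counts,
        "tpm": tpm,
        "genes": genes,
        "bulk": bulk,
        "truth": truth,
        "log2tpm": nc.log2_tpm(tpm),
    }


@pytest.fixture()
def tiny_genes():
    return {
        nc.GeneRecord("g1", "coding", 1000),
        nc.GeneRecord("g2", "coding", 2000),
        nc.GeneRecord("n1", "tRNA", 80),
        nc.GeneRecord("n2", "lincRNA", 500),
    }


def make_matrix(values, gene_ids, cell_ids, kind="counts"):
    return nc.ExpressionMatrix(np.asarray(values, float), gene_ids, cell_ids, kind)
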