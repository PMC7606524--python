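"""Recovery benchmarks: the study conditions exercised end to end.

Each function generates a synthetic embryo dataset under the default
conditions, runs the corresponding pipeline stage, and measures how well
the planted ground truth is recovered.  They are used both by the
acceptance test-suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from . import clustering, coexpression, markers, profile, staging, trends
from .simulate import SimulationConfig, simulate
from .types import NCRNA_CLASSES


#: published per-biotype detection accounting for the 1031-cell *C. elegans*
#: embryo dataset (SRA SRP112706): (detected, annotated) pairs and the
#: per-class detected counts.  These printed values are inputs to the
#: arithmetic checks, not outputs of this package.
PUBLISHED_DETECTION = {
    "protein_coding_text": (20436, 20447),
    "protein_coding_table": (20431, 20447),
    "tRNA": (571, 637),
    "pseudogene": (1546, 1590),
    "all_ncRNA": (9843, 10679),
}

PUBLISHED_NCRNA_CLASS_COUNTS = {
    "antisense": 99,
    "lincRNA": 169,
    "rRNA": 22,
    "snoRNA": 338,
    "pseudogene": 1546,
    "snRNA": 126,
    "tRNA": 571,
    "unknown_ncRNA": 6972,
}

PUBLISHED_NEW_MARKERS = {"coding": 22, "ncRNA": 11}


def table1_arithmetic() -> dict:
    """Detection-accounting arithmetic on the published counts."""
    ratios = {
        name: profile.detect_ratio(*pair) for name, pair in PUBLISHED_DETECTION.items()
    }
    return {
        "detect_ratio_protein_coding_pct": ratios["protein_coding_text"],
        "detect_ratio_trna_pct": ratios["tRNA"],
        "detect_ratio_pseudogene_pct": ratios["pseudogene"],
        "detect_ratio_all_ncrna_pct": ratios["all_ncRNA"],
        "ncrna_detected_total": int(sum(PUBLISHED_NCRNA_CLASS_COUNTS.values())),
        "new_marker_total": int(sum(PUBLISHED_NEW_MARKERS.values())),
    }


def staging_recovery(seed: int = 11, n_cells: int = 500) -> dict:
    """Spearman agreement between true and estimated embryo times, with the
    default noise model (dropout on)."""
    cfg = SimulationConfig(n_cells=n_cells, seed=seed)
    _, tpm, _, bulk, truth = simulate(cfg)
    results = staging.stage_cells(profile.log2_tpm(tpm), bulk)
    estimated = np.array([r.embryo_time_min for r in results])
    rho = spearmanr(truth.embryo_time_min, estimated).statistic
    return {
        "spearman_rho": float(rho),
        "median_abs_error_min": float(np.median(np.abs(estimated - truth.embryo_time_min))),
        "n_cells": n_cells,
    }


def hub_recovery(seed: int = 17, n_cells: int = 800) -> dict:
    """Precision/recall of the >=4-partner screen against planted hubs."""
    cfg = SimulationConfig(n_cells=n_cells, seed=seed)  # 6 pos + 2 neg hubs
    _, tpm, genes, _, truth = simulate(cfg)
    edges = coexpression.screen_pairs(profile.log2_tpm(tpm), genes)
    hubs = coexpression.select_hubs(edges)
    found = {h.ncrna_id for h in hubs if h.passes}
    planted = {h.ncrna_id for h in truth.hubs}
    tp = len(found & planted)
    return {
        "precision": tp / len(found) if found else 0.0,
        "recall": tp / len(planted),
        "n_edges": len(edges),
        "n_cells": n_cells,
        "n_planted_hubs": len(planted),
    }


def marker_recovery(seed: int = 9, n_cells: int = 600, n_permutations: int = 5) -> dict:
    """Planted-marker recall on true type labels, plus the count of
    Bonferroni-significant markers under label permutation."""
    cfg = SimulationConfig(n_cells=n_cells, seed=seed)
    counts, *_ , truth = simulate(cfg)
    norm = clustering.log_normalize(counts)
    types = np.array(truth.cell_types)
    records = markers.find_all_markers(norm, types)
    n_planted = n_found = 0
    for cell_type, planted in truth.markers.items():
        significant = {r.gene_id for r in records
                       if r.cluster == cell_type and r.p_adj < 0.05}
        n_planted += len(planted)
        n_found += len(set(planted) & significant)
    rng = np.random.default_rng(seed)
    permuted_hits = 0
    for _ in range(n_permutations):
        shuffled = rng.permutation(types)
        permuted_hits += sum(
            r.p_adj < 0.05 for r in markers.find_all_markers(norm, shuffled)
        )
    return {
        "recall": n_found / n_planted,
        "n_planted": n_planted,
        "permuted_significant": int(permuted_hits),
        "n_cells": n_cells,
    }


def trend_recovery(seed: int = 23, n_cells: int = 600, n_shuffles: int = 3) -> dict:
    """Planted decliner recall on staged times and the false-flag rate
    under time shuffling."""
    cfg = SimulationConfig(n_cells=n_cells, seed=seed)
    _, tpm, _, bulk, truth = simulate(cfg)
    lg = profile.log2_tpm(tpm)
    estimated = np.array(
        [r.embryo_time_min for r in staging.stage_cells(lg, bulk)]
    )
    flagged = {f.gene_id for f in trends.detect_decreasing(lg, estimated)}
    planted = set(truth.trend_genes)
    rng = np.random.default_rng(seed)
    null_rates = []
    for _ in range(n_shuffles):
        shuffled = rng.permutation(estimated)
        null_rates.append(len(trends.detect_decreasing(lg, shuffled)) / lg.n_genes)
    return {
        "recall": len(flagged & planted) / len(planted),
        "n_planted": len(planted),
        "null_flag_pct_max": 100.0 * max(null_rates),
        "n_cells": n_cells,
    }


def ncrna_feature_advantage(seed: int = 0, n_seeds: int = 20, n_cells: int = 400) -> dict:
    """The ncRNA-defined cell type: how often ncRNA-only clustering beats
    coding-only clustering at recovering it (ARI against its indicator)."""
    from sklearn.metrics import adjusted_rand_score

    wins = 0
    diffs = []
    for k in range(n_seeds):
        cfg = SimulationConfig(n_cells=n_cells, seed=seed + k)
        counts, _, genes, _, truth = simulate(cfg)
        ccfg = clustering.ClusteringConfig(seed=seed + k)
        lab_nc = clustering.run_feature_set_clustering(counts, genes, "ncrna", ccfg)
        lab_cod = clustering.run_feature_set_clustering(counts, genes, "coding", ccfg)
        indicator = np.array([t == truth.ncrna_only_type for t in truth.cell_types])
        ari_nc = adjusted_rand_score(lab_nc, indicator)
        ari_cod = adjusted_rand_score(lab_cod, indicator)
        wins += ari_nc > ari_cod
        diffs.append(ari_nc - ari_cod)
    return {
        "wins": int(wins),
        "n_seeds": n_seeds,
        "mean_ari_difference": float(np.mean(diffs)),
        "n_cells": n_cells,
    }


def pipeline_determinism(outdir, seed: int = 4, n_cells: int = 150) -> dict:
    """Run the full pipeline twice from one config; compare file checksums."""
    from pathlib import Path

    from .pipeline import PipelineConfig, run

    outdir = Path(outdir)
    manifests = []
    for sub in ("a", "b"):
        cfg = PipelineConfig(
            outdir=str(outdir / sub), seed=seed,
            simulate_params={"n_cells": n_cells},
        )
        manifests.append(run(cfg))
    identical = manifests[0]["files"] == manifests[1]["files"]
    return {"identical": bool(identical), "n_files": len(manifests[0]["files"]),
            "n_cells": n_cells}
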