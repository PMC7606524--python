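"""Synthetic embryo dataset with recoverable ground truth.

The generator emulates the statistical structure the downstream stages
assume: ~1000 cells drawn from a handful of embryonic cell types over a
150-800 min time range, a gene panel partitioned into protein-coding genes
and eight ncRNA classes, a noise-free 10-timepoint bulk reference, planted
cluster-specific markers, positively and negatively co-expressed ncRNA
hubs, genes with smooth time-dependent profiles (used for staging) and
genes whose expression declines monotonically over 270-830 min.

One cell type ("muscle" by default) carries its identity exclusively in
ncRNA expression: on coding genes each of its cells mimics a disguise type
drawn from the other differentiated types, so coding-only clustering
scatters it while ncRNA-only clustering isolates it.

Counts are negative-binomial (gamma-Poisson) around per-cell depth-scaled
means, thinned by logistic dropout in log mean; TPM follows from counts and
gene lengths.  Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .profile import compute_tpm
from .types import (
    NCRNA_CLASSES,
    BulkTimeCourse,
    ExpressionMatrix,
    GeneRecord,
    HubSpec,
    SyntheticTruth,
)

#: typical transcript lengths (bp) by biotype used when drawing gene lengths
_LENGTH_SCALE = {
    "coding": 1500,
    "antisense": 600,
    "lincRNA": 800,
    "rRNA": 1500,
    "snoRNA": 100,
    "pseudogene": 1000,
    "snRNA": 150,
    "tRNA": 75,
    "unknown_ncRNA": 300,
}


@dataclass
class CellTypeSpec:
    name: str
    proportion: float
    n_marker_genes: int = 25
    marker_ln_fc: float = 1.0


def default_cell_types() -> list[CellTypeSpec]:
    return [
        CellTypeSpec("intestine_anterior", 0.12),
        CellTypeSpec("intestine_posterior", 0.12),
        CellTypeSpec("pharynx", 0.20),
        CellTypeSpec("hypodermis", 0.15),
        CellTypeSpec("muscle", 0.08, n_marker_genes=30, marker_ln_fc=2.0),
        CellTypeSpec("undifferentiated_early", 0.33),
    ]


@dataclass
class SimulationConfig:
    n_cells: int = 1031
    n_coding: int = 2000
    n_ncrna_per_class: dict = field(
        default_factory=lambda: {
            "antisense": 20,
            "lincRNA": 30,
            "rRNA": 5,
            "snoRNA": 40,
            "pseudogene": 150,
            "snRNA": 15,
            "tRNA": 60,
            "unknown_ncRNA": 300,
        }
    )
    cell_types: list = field(default_factory=default_cell_types)
    time_range_min: tuple = (150.0, 800.0)
    bulk_timepoints_min: list = field(
        default_factory=lambda: [100, 210, 300, 360, 420, 480, 545, 635, 725, 800]
    )
    n_time_variable_genes: int = 200
    n_hubs_pos: int = 6
    n_hubs_neg: int = 2
    partners_per_hub: int = 6
    hub_latent_sd: float = 1.2
    n_trend_genes: int = 20
    n_trend_ncrna: int = 4
    trend_decline_log2: float = 1.5
    trend_window_min: tuple = (270.0, 830.0)
    nb_dispersion: float = 0.1
    dropout: bool = True
    dropout_midpoint: float = 0.0
    dropout_slope: float = 2.0
    mean_depth: float = 50_000.0
    depth_sigma: float = 0.3
    ncrna_only_type: str | None = "muscle"
    disguise_types: tuple = ("pharynx", "hypodermis")
    seed: int = 0

    def validate(self) -> None:
        props = sum(ct.proportion for ct in self.cell_types)
        if abs(props - 1.0) > 1e-9:
            raise ValueError(f"cell type proportions must sum to 1, got {props}")
        if self.partners_per_hub < 1:
            raise ValueError("partners_per_hub must be >= 1")
        for name, n in self.n_ncrna_per_class.items():
            if name not in NCRNA_CLASSES:
                raise ValueError(f"unknown ncRNA class {name!r}")
            if n < 0:
                raise ValueError("gene counts must be >= 0")
        if self.n_coding < 0 or self.n_cells < 1:
            raise ValueError("n_coding must be >= 0 and n_cells >= 1")
        names = [ct.name for ct in self.cell_types]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cell type names")
        if self.ncrna_only_type is not None:
            if self.ncrna_only_type not in names:
                raise ValueError(f"ncrna_only_type {self.ncrna_only_type!r} not a cell type")
            for d in self.disguise_types:
                if d not in names or d == self.ncrna_only_type:
                    raise ValueError(f"invalid disguise type {d!r}")


def _draw_genes(cfg: SimulationConfig, rng: np.random.Generator) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    for i in range(cfg.n_coding):
        length = max(int(rng.lognormal(np.log(_LENGTH_SCALE["coding"]), 0.5)), 50)
        genes.append(GeneRecord(f"cg{i:05d}", "coding", length))
    for cls in NCRNA_CLASSES:
        for i in range(cfg.n_ncrna_per_class.get(cls, 0)):
            length = max(int(rng.lognormal(np.log(_LENGTH_SCALE[cls]), 0.5)), 20)
            genes.append(GeneRecord(f"nc_{cls}_{i:04d}", cls, length))
    return genes


def simulate(
    config: SimulationConfig | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, set[GeneRecord], BulkTimeCourse, SyntheticTruth]:
    """Generate (counts, TPM, annotation, bulk time course, planted truth)."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes = _draw_genes(cfg, rng)
    gene_ids = [g.gene_id for g in genes]
    n_genes = len(gene_ids)
    coding_ids = [g.gene_id for g in genes if g.biotype == "coding"]
    ncrna_ids = [g.gene_id for g in genes if g.biotype != "coding"]
    lengths = np.array([g.length_bp for g in genes], dtype=float)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    # --- assign special gene roles from disjoint pools -------------------
    coding_pool = list(coding_ids)
    ncrna_pool = list(ncrna_ids)
    rng.shuffle(coding_pool)
    rng.shuffle(ncrna_pool)

    def take(pool: list, n: int, what: str) -> list:
        if n > len(pool):
            raise ValueError(f"infeasible config: not enough genes left for {what}")
        out = pool[:n]
        del pool[:n]
        return out

    markers: dict[str, list[str]] = {}
    for ct in cfg.cell_types:
        if cfg.ncrna_only_type == ct.name:
            markers[ct.name] = take(ncrna_pool, ct.n_marker_genes, f"{ct.name} markers")
        else:
            markers[ct.name] = take(coding_pool, ct.n_marker_genes, f"{ct.name} markers")

    hubs: list[HubSpec] = []
    for h in range(cfg.n_hubs_pos + cfg.n_hubs_neg):
        sign = "pos" if h < cfg.n_hubs_pos else "neg"
        nid = take(ncrna_pool, 1, "hub ncRNAs")[0]
        partners = take(coding_pool, cfg.partners_per_hub, "hub partners")
        hubs.append(HubSpec(ncrna_id=nid, partner_ids=partners, sign=sign))

    n_trend_coding = max(cfg.n_trend_genes - cfg.n_trend_ncrna, 0)
    trend_ids = take(coding_pool, n_trend_coding, "trend genes") + take(
        ncrna_pool, min(cfg.n_trend_ncrna, cfg.n_trend_genes), "trend ncRNAs"
    )
    trend_genes = {g: float(cfg.trend_decline_log2) for g in trend_ids}

    time_variable = take(coding_pool, cfg.n_time_variable_genes, "time-variable genes")

    # --- baseline rates ---------------------------------------------------
    baseline = rng.lognormal(mean=1.0, sigma=1.2, size=n_genes)
    is_ncrna = np.array([g.biotype != "coding" for g in genes])
    baseline[is_ncrna] *= 0.5  # ncRNAs generally lower expressed
    for hub in hubs:  # hub genes are well-expressed so the screen can see them
        for g in [hub.ncrna_id, *hub.partner_ids]:
            baseline[gene_pos[g]] = rng.lognormal(mean=3.0, sigma=0.3)
    for gene_list in markers.values():
        for g in gene_list:
            baseline[gene_pos[g]] = rng.lognormal(mean=2.0, sigma=0.5)
    for g in trend_ids:
        baseline[gene_pos[g]] = rng.lognormal(mean=2.5, sigma=0.3)

    # --- temporal profiles ------------------------------------------------
    tv_idx = np.array([gene_pos[g] for g in time_variable], dtype=int)
    tv_amp = rng.uniform(1.0, 2.0, size=tv_idx.size) * rng.choice(
        [-1.0, 1.0], size=tv_idx.size
    )
    tv_mid = rng.uniform(180.0, 760.0, size=tv_idx.size)
    tv_tau = rng.uniform(30.0, 80.0, size=tv_idx.size)
    trend_idx = np.array([gene_pos[g] for g in trend_ids], dtype=int)
    w_lo, w_hi = cfg.trend_window_min

    def temporal_factor(t: np.ndarray) -> np.ndarray:
        """genes x len(t) multiplicative factor (1 for untouched genes)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        F = np.ones((n_genes, t.size))
        F[tv_idx] = np.exp(tv_amp[:, None] * expit((t[None, :] - tv_mid[:, None]) / tv_tau[:, None]))
        frac = np.clip((t[None, :] - w_lo) / (w_hi - w_lo), 0.0, 1.0)
        F[trend_idx] = 2.0 ** (-cfg.trend_decline_log2 * frac)
        return F

    # --- cells ------------------------------------------------------------
    type_names = [ct.name for ct in cfg.cell_types]
    proportions = np.array([ct.proportion for ct in cfg.cell_types])
    cell_type_idx = rng.choice(len(type_names), size=cfg.n_cells, p=proportions)
    cell_types = [type_names[i] for i in cell_type_idx]
    times = rng.uniform(cfg.time_range_min[0], cfg.time_range_min[1], size=cfg.n_cells)
    cell_ids = [f"cell{j:04d}" for j in range(cfg.n_cells)]

    mu = baseline[:, None] * temporal_factor(times)  # genes x cells

    # marker boosts; the ncRNA-only type additionally wears a coding disguise.
    # Its ncRNA marker boost redistributes expression WITHIN the ncRNA
    # compartment (compartment total preserved), so on coding genes — and on
    # total output — such cells are exact copies of their disguise type.
    boost_by_type = {ct.name: float(np.exp(ct.marker_ln_fc)) for ct in cfg.cell_types}
    nc_rows = np.flatnonzero(is_ncrna)
    disguises: dict[str, str] = {}
    for j, ct_name in enumerate(cell_types):
        if cfg.ncrna_only_type == ct_name:
            d = cfg.disguise_types[int(rng.integers(len(cfg.disguise_types)))]
            disguises[cell_ids[j]] = d
            for g in markers[d]:
                mu[gene_pos[g], j] *= boost_by_type[d]
            nc_before = mu[nc_rows, j].sum()
            for g in markers[ct_name]:
                mu[gene_pos[g], j] *= boost_by_type[ct_name]
            mu[nc_rows, j] *= nc_before / mu[nc_rows, j].sum()
        else:
            for g in markers[ct_name]:
                mu[gene_pos[g], j] *= boost_by_type[ct_name]

    # hub latents: multiplicative log-normal co-expression
    for hub in hubs:
        a = rng.normal(0.0, cfg.hub_latent_sd, size=cfg.n_cells)
        mu[gene_pos[hub.ncrna_id]] *= np.exp(a)
        s = 1.0 if hub.sign == "pos" else -1.0
        for g in hub.partner_ids:
            mu[gene_pos[g]] *= np.exp(s * a)

    # --- counts: gamma-Poisson + logistic dropout --------------------------
    depth = rng.lognormal(np.log(cfg.mean_depth), cfg.depth_sigma, size=cfg.n_cells)
    mu_norm = mu / mu.sum(axis=0, keepdims=True)
    mean_counts = mu_norm * depth[None, :]
    if cfg.nb_dispersion > 1e-12:
        shape = 1.0 / cfg.nb_dispersion
        lam = rng.gamma(shape, mean_counts * cfg.nb_dispersion)
        counts = rng.poisson(lam).astype(float)
    else:
        counts = rng.poisson(mean_counts).astype(float)
    if cfg.dropout:
        p_drop = expit(
            -(np.log(mean_counts + 1e-12) - cfg.dropout_midpoint) * cfg.dropout_slope
        )
        counts *= rng.random(counts.shape) >= p_drop

    counts_matrix = ExpressionMatrix(counts, gene_ids, cell_ids, "counts")
    tpm_matrix = compute_tpm(counts_matrix, genes)

    # --- noise-free bulk reference ----------------------------------------
    bulk_t = np.asarray(cfg.bulk_timepoints_min, dtype=float)
    F = temporal_factor(bulk_t)
    type_boost = np.ones((n_genes, len(type_names)))
    for k, ct in enumerate(cfg.cell_types):
        for g in markers[ct.name]:
            type_boost[gene_pos[g], k] = boost_by_type[ct.name]
        if cfg.ncrna_only_type == ct.name:
            for d in cfg.disguise_types:
                for g in markers[d]:
                    type_boost[gene_pos[g], k] *= boost_by_type[d] ** (
                        1.0 / len(cfg.disguise_types)
                    )
            # mirror the compartment-preserving ncRNA boost in the reference
            nc_rows_k = np.flatnonzero(is_ncrna)
            before = baseline[nc_rows_k].sum()
            after = (baseline[nc_rows_k] * type_boost[nc_rows_k, k]).sum()
            type_boost[nc_rows_k, k] *= before / after
    pop_boost = type_boost @ proportions  # population-mean marker boost
    hub_factor = np.ones(n_genes)
    ea = float(np.exp(cfg.hub_latent_sd**2 / 2.0))  # E[e^{+-a}]
    for hub in hubs:
        hub_factor[gene_pos[hub.ncrna_id]] *= ea
        for g in hub.partner_ids:
            hub_factor[gene_pos[g]] *= ea
    mu_bulk = baseline[:, None] * pop_boost[:, None] * hub_factor[:, None] * F
    rate = mu_bulk / lengths[:, None]
    bulk_tpm = 1e6 * rate / rate.sum(axis=0, keepdims=True)
    bulk = BulkTimeCourse(
        gene_ids=gene_ids,
        timepoints_min=bulk_t,
        values=np.log2(bulk_tpm + 1.0),
        time_variable_genes=list(time_variable),
    )

    truth = SyntheticTruth(
        cell_ids=cell_ids,
        cell_types=cell_types,
        embryo_time_min=times,
        hubs=hubs,
        markers=markers,
        trend_genes=trend_genes,
        time_variable_genes=list(time_variable),
        ncrna_only_type=cfg.ncrna_only_type,
        disguise_types=disguises,
        bulk=bulk,
    )
    return counts_matrix, tpm_matrix, set(genes), bulk, truth


# ---------------------------------------------------------------------------
# truth serialization


def truth_report(truth: SyntheticTruth, outdir: str | Path) -> None:
    """Serialize the planted truth as delimited tables under ``outdir``."""
    outdir = Path(outdir)
    if not outdir.is_dir():
        raise FileNotFoundError(f"directory {outdir} does not exist")
    cells = pd.DataFrame(
        {
            "cell_id": truth.cell_ids,
            "cell_type": truth.cell_types,
            "embryo_time_min": truth.embryo_time_min,
            "disguise": [truth.disguise_types.get(c, "") for c in truth.cell_ids],
        }
    )
    cells.to_csv(outdir / "truth_cells.tsv", sep="\t", index=False, float_format="%.17g")
    hubs = pd.DataFrame(
        [
            {"ncrna_id": h.ncrna_id, "sign": h.sign, "partners": ";".join(h.partner_ids)}
            for h in truth.hubs
        ],
        columns=["ncrna_id", "sign", "partners"],
    )
    hubs.to_csv(outdir / "truth_hubs.tsv", sep="\t", index=False)
    marker_rows = [
        {"cell_type": ct, "gene_id": g} for ct, gl in truth.markers.items() for g in gl
    ]
    pd.DataFrame(marker_rows, columns=["cell_type", "gene_id"]).to_csv(
        outdir / "truth_markers.tsv", sep="\t", index=False
    )
    trends = pd.DataFrame(
        [{"gene_id": g, "decline_log2": a} for g, a in truth.trend_genes.items()],
        columns=["gene_id", "decline_log2"],
    )
    trends.to_csv(outdir / "truth_trends.tsv", sep="\t", index=False, float_format="%.17g")
    with open(outdir / "truth_time_variable.tsv", "w") as fh:
        fh.write("gene_id\n")
        for g in truth.time_variable_genes:
            fh.write(g + "\n")
    with open(outdir / "truth_meta.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"ncrna_only_type\t{truth.ncrna_only_type or ''}\n")


def read_truth(outdir: str | Path) -> SyntheticTruth:
    """Read back a truth report written by :func:`truth_report`."""
    outdir = Path(outdir)
    cells = pd.read_csv(outdir / "truth_cells.tsv", sep="\t", keep_default_na=False)
    hubs_df = pd.read_csv(outdir / "truth_hubs.tsv", sep="\t")
    markers_df = pd.read_csv(outdir / "truth_markers.tsv", sep="\t")
    trends_df = pd.read_csv(outdir / "truth_trends.tsv", sep="\t")
    tv = pd.read_csv(outdir / "truth_time_variable.tsv", sep="\t")
    meta = dict(
        pd.read_csv(outdir / "truth_meta.tsv", sep="\t", keep_default_na=False).values
    )
    hubs = [
        HubSpec(
            ncrna_id=r.ncrna_id,
            partner_ids=r.partners.split(";") if r.partners else [],
            sign=r.sign,
        )
        for r in hubs_df.itertuples()
    ]
    markers: dict[str, list[str]] = {}
    for r in markers_df.itertuples():
        markers.setdefault(r.cell_type, []).append(r.gene_id)
    disguises = {
        r.cell_id: r.disguise for r in cells.itertuples() if r.disguise
    }
    return SyntheticTruth(
        cell_ids=list(cells["cell_id"].astype(str)),
        cell_types=list(cells["cell_type"].astype(str)),
        embryo_time_min=cells["embryo_time_min"].to_numpy(float),
        hubs=hubs,
        markers=markers,
        trend_genes={r.gene_id: float(r.decline_log2) for r in trends_df.itertuples()},
        time_variable_genes=list(tv["gene_id"].astype(str)),
        ncrna_only_type=meta.get("ncrna_only_type") or None,
        disguise_types=disguises,
        bulk=None,
    )
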