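"""End-to-end orchestration of the analysis stages.

A run is driven by a :class:`PipelineConfig` (optionally read from a flat
key-value YAML file with stage-prefixed keys, e.g. ``simulate.n_cells``),
executes the requested stages in dependency order — inserting implicit
upstream dependencies — and records every produced file in a manifest with
checksums and a parameter snapshot.  Re-running an identical config
reproduces byte-identical outputs: the global seed fans out to per-stage
seeds derived by hashing the stage name, so inserting a stage does not
shift the randomness of the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, coexpression, io, markers, profile, staging, trends
from .simulate import SimulationConfig, simulate as run_simulation, truth_report
from .types import NCRNA_CLASSES

log = logging.getLogger(__name__)

STAGES = ("simulate", "profile", "stage_time", "cluster", "markers", "coexpr", "trends")

#: upstream stages each stage needs (profile is satisfied by matrix inputs
#: or by simulate; stage_time additionally needs a bulk course)
_DEPS = {
    "simulate": (),
    "profile": (),
    "stage_time": ("profile",),
    "cluster": (),
    "markers": ("cluster",),
    "coexpr": ("profile",),
    "trends": ("stage_time", "profile"),
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: global seed XOR a hash of the stage name, < 2**31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    outdir: str = "ncembryo_out"
    stages: list = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    # external inputs (each optional when `simulate` is requested)
    matrix_path: str | None = None
    annotation_path: str | None = None
    annotation_format: str = "two_column_tsv"
    bulk_path: str | None = None
    bulk_time_variable_path: str | None = None
    exclusion_list_path: str | None = None
    # stage parameter blocks
    simulate_params: dict = field(default_factory=dict)
    staging_span: float = 0.75
    clustering_params: dict = field(default_factory=dict)
    marker_min_pct: float = 0.75
    marker_ln_fc_min: float = 0.25
    coexpr_r_min: float = 0.6
    coexpr_p_max: float = 1e-5
    coexpr_min_partners: int = 4
    trend_span: float = 0.5
    trend_window_min: tuple = (270.0, 830.0)
    trend_min_decline: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Flat key-value config: top-level keys, plus stage-prefixed keys
        like ``simulate.n_cells`` or ``clustering.resolution``."""
        raw = yaml.safe_load(open(path)) or {}
        cfg = cls()
        for key, value in raw.items():
            if "." in key:
                prefix, name = key.split(".", 1)
                if prefix == "simulate":
                    cfg.simulate_params[name] = value
                elif prefix == "clustering":
                    cfg.clustering_params[name] = value
                elif prefix == "staging" and name == "span":
                    cfg.staging_span = float(value)
                elif prefix == "marker":
                    setattr(cfg, f"marker_{name}", value)
                elif prefix == "coexpr":
                    setattr(cfg, f"coexpr_{name}", value)
                elif prefix == "trend":
                    setattr(cfg, f"trend_{name}", value)
                else:
                    raise ValueError(f"unknown config key {key!r}")
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cfg

    def resolve_stages(self) -> list:
        """Requested stages plus implicit dependencies, in pipeline order."""
        wanted = set(self.stages)
        unknown = wanted - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        changed = True
        while changed:
            changed = False
            for s in list(wanted):
                for dep in _DEPS[s]:
                    if dep not in wanted:
                        wanted.add(dep)
                        changed = True
        if "simulate" not in wanted:
            if ("profile" in wanted or "cluster" in wanted) and not (
                self.matrix_path and self.annotation_path
            ):
                raise ValueError(
                    "profile/cluster need matrix_path and annotation_path, "
                    "or the simulate stage"
                )
            if "stage_time" in wanted and not self.bulk_path:
                raise ValueError("stage_time needs bulk_path or the simulate stage")
        return [s for s in STAGES if s in wanted]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.resolve_stages()
    log.info("running stages: %s", stages)

    produced: list[Path] = []
    ctx: dict = {}

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        produced.append(path)

    if "simulate" in stages:
        params = dict(config.simulate_params)
        params.setdefault("seed", stage_seed(config.seed, "simulate"))
        sim_cfg = SimulationConfig(**params)
        counts, tpm, genes, bulk, truth = run_simulation(sim_cfg)
        ctx.update(counts=counts, tpm=tpm, genes=genes, bulk=bulk, truth=truth)
        emit("counts.tsv", lambda p: io.write_matrix(counts, p))
        emit("annotation.tsv", lambda p: io.write_annotation(genes, p))
        emit(
            "bulk.tsv",
            lambda p: pd.DataFrame(
                bulk.values, index=bulk.gene_ids, columns=bulk.timepoints_min
            ).to_csv(p, sep="\t", float_format="%.17g"),
        )
        truth_dir = outdir / "truth"
        truth_dir.mkdir(exist_ok=True)
        truth_report(truth, truth_dir)
        produced.extend(sorted(truth_dir.iterdir()))
    else:
        if config.matrix_path:
            ctx["counts"] = io.read_matrix(config.matrix_path, kind="counts")
        if config.annotation_path:
            ctx["genes"] = io.read_annotation(
                config.annotation_path, config.annotation_format
            )
        if config.bulk_path:
            df = pd.read_csv(config.bulk_path, sep="\t", index_col=0)
            tv = [
                l.strip()
                for l in open(config.bulk_time_variable_path)
                if l.strip() and l.strip() != "gene_id"
            ]
            from .types import BulkTimeCourse

            ctx["bulk"] = BulkTimeCourse(
                gene_ids=list(df.index.astype(str)),
                timepoints_min=df.columns.astype(float).to_numpy(),
                values=df.to_numpy(float),
                time_variable_genes=tv,
            )

    if "profile" in stages:
        if "tpm" not in ctx:
            ctx["tpm"] = profile.compute_tpm(ctx["counts"], ctx["genes"])
        ctx["log2tpm"] = profile.log2_tpm(ctx["tpm"])
        summary = profile.detection_summary(ctx["tpm"], ctx["genes"])
        emit("detection_summary.tsv", lambda p: io.write_table(summary, p))

    if "stage_time" in stages:
        results = staging.stage_cells(ctx["log2tpm"], ctx["bulk"], span=config.staging_span)
        table = staging.staging_table(results)
        ctx["staging"] = table
        emit("staging.tsv", lambda p: io.write_table(table, p))
        annotation = table.rename(columns={"interval": "time_interval"})
        corr = profile.per_interval_detection_correlation(
            ctx["tpm"], ctx["genes"], annotation
        )
        emit("interval_detection_correlation.tsv", lambda p: io.write_table(corr, p))

    if "cluster" in stages:
        params = dict(config.clustering_params)
        params.setdefault("seed", stage_seed(config.seed, "cluster"))
        base = clustering.ClusteringConfig(**params)
        labels = {}
        for fs in ("combined", "coding", "ncrna"):
            cfg_fs = dataclasses.replace(base, feature_set=fs)
            labels[fs] = clustering.run_feature_set_clustering(
                ctx["counts"], ctx["genes"], fs, cfg_fs
            )
        ctx["labels"] = labels
        df = pd.DataFrame(
            {
                "cell_id": ctx["counts"].cell_ids,
                "cluster_combined": labels["combined"],
                "cluster_coding": labels["coding"],
                "cluster_ncrna": labels["ncrna"],
            }
        )
        emit("clusters.tsv", lambda p: io.write_table(df, p))
        comp = clustering.compare_partitions(labels["combined"], labels["ncrna"])
        long = comp.contingency.stack().reset_index()
        long.columns = ["cluster_combined", "cluster_ncrna", "n_cells"]
        long["ari_combined_vs_ncrna"] = comp.adjusted_rand_index
        emit("cluster_comparison.tsv", lambda p: io.write_table(long, p))

    if "markers" in stages:
        norm = clustering.log_normalize(ctx["counts"])
        recs = markers.find_all_markers(
            norm,
            ctx["labels"]["combined"],
            min_pct=config.marker_min_pct,
            ln_fc_min=config.marker_ln_fc_min,
        )
        rows = []
        for cluster in sorted({r.cluster for r in recs}):
            for rank, r in enumerate(
                markers.top_markers([m for m in recs if m.cluster == cluster]), 1
            ):
                rows.append({**dataclasses.asdict(r), "rank": rank})
        cols = ["cluster", "gene_id", "ln_fc", "pct_in", "pct_out", "p", "p_adj", "rank"]
        df = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
        emit("markers.tsv", lambda p: io.write_table(df, p))

    if "coexpr" in stages:
        edges = coexpression.screen_pairs(
            ctx["log2tpm"], ctx["genes"], r_min=config.coexpr_r_min,
            p_max=config.coexpr_p_max,
        )
        hubs = coexpression.select_hubs(
            edges, min_partners=config.coexpr_min_partners,
            partner_p_max=config.coexpr_p_max,
        )
        emit("edges.tsv", lambda p: io.write_table(coexpression.edges_table(edges), p))
        hub_df = pd.DataFrame(
            [
                {
                    "ncrna_id": h.ncrna_id,
                    "n_pos": h.n_pos_partners,
                    "n_neg": h.n_neg_partners,
                    "passes": h.passes,
                    "partners": ";".join(h.partner_ids),
                }
                for h in hubs
            ],
            columns=["ncrna_id", "n_pos", "n_neg", "passes", "partners"],
        )
        emit("hubs.tsv", lambda p: io.write_table(hub_df, p))
        emit(
            "hub_report.tsv",
            lambda p: io.write_table(coexpression.hub_report(hubs, edges), p),
        )

    if "trends" in stages:
        exclude = []
        if config.exclusion_list_path:
            exclude = [l.strip() for l in open(config.exclusion_list_path) if l.strip()]
        times = ctx["staging"]["embryo_time_min"].to_numpy(float)
        fits = trends.detect_decreasing(
            ctx["log2tpm"],
            times,
            window_min=tuple(config.trend_window_min),
            span=config.trend_span,
            min_decline=config.trend_min_decline,
            exclude=exclude,
        )
        gene_index = {g.gene_id: g for g in ctx["genes"]}
        df = pd.DataFrame(
            [
                {
                    "gene_id": f.gene_id,
                    "biotype": gene_index[f.gene_id].biotype,
                    "total_decline": f.total_decline,
                    "monotone_decreasing": f.monotone_decreasing,
                }
                for f in fits
            ],
            columns=["gene_id", "biotype", "total_decline", "monotone_decreasing"],
        )
        emit("trends.tsv", lambda p: io.write_table(df, p))

    manifest = {
        "stages": stages,
        "seed": config.seed,
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("outdir",)
        },
        "files": {
            str(p.relative_to(outdir)): {"sha256": _sha256(p)} for p in produced
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def summarize(manifest: dict | str | Path, outdir: str | Path | None = None) -> str:
    """Human-readable run report from a manifest (or its path)."""
    if not isinstance(manifest, dict):
        path = Path(manifest)
        outdir = outdir or path.parent
        try:
            manifest = json.load(open(path))
        except (OSError, json.JSONDecodeError) as exc:
            raise ValueError(f"cannot read manifest: {exc}") from exc
    if not manifest.get("files"):
        log.warning("manifest lists no files")
        return "empty run (no files produced)\n"
    lines = [f"stages: {', '.join(manifest['stages'])}", f"seed: {manifest['seed']}"]
    for name in sorted(manifest["files"]):
        lines.append(f"  {name}  sha256:{manifest['files'][name]['sha256'][:12]}")
        if outdir and name.endswith(".tsv"):
            try:
                n = len(pd.read_csv(Path(outdir) / name, sep="\t"))
                lines[-1] += f"  rows:{n}"
            except Exception:
                pass
    if outdir and "detection_summary.tsv" in manifest["files"]:
        lines.append("detection summary:")
        det = pd.read_csv(Path(outdir) / "detection_summary.tsv", sep="\t")
        lines.append(det.to_string(index=False))
    return "\n".join(lines) + "\n"
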