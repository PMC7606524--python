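"""Quantification transforms and per-biotype detection accounting.

TPM is length-normalized expression scaled so every cell sums to one
million; a gene counts as *detected* in a cell when its TPM is strictly
greater than 1, and as detected in the dataset when it is detected in at
least one cell.  The detection summary mirrors the classic per-biotype
table: per-cell median (min-max) of detected genes, total detected, total
annotated and the detect ratio in percent.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import BIOTYPES, NCRNA_CLASSES, TPM_TOTAL, ExpressionMatrix, GeneRecord, genes_by_id

log = logging.getLogger(__name__)


def compute_tpm(counts: ExpressionMatrix, genes: Iterable[GeneRecord]) -> ExpressionMatrix:
    """Transcripts-per-million from raw counts and gene lengths.

    Per cell: rate_g = count_g / length_g; TPM_g = 1e6 * rate_g / sum(rate).
    Cells with zero total counts yield all-zero columns (warned, not fatal).
    """
    if counts.kind != "counts":
        raise ValueError(f"expected a counts matrix, got kind={counts.kind!r}")
    index = genes_by_id(genes)
    missing = [g for g in counts.gene_ids if g not in index]
    if missing:
        raise KeyError(f"no gene length for {missing[0]!r} ({len(missing)} genes missing)")
    lengths = np.array([index[g].length_bp for g in counts.gene_ids], dtype=float)
    rates = counts.values / lengths[:, None]
    totals = rates.sum(axis=0)
    empty = totals == 0
    if empty.any():
        log.warning("%d all-zero cell(s) produce all-zero TPM columns", int(empty.sum()))
    safe = np.where(empty, 1.0, totals)
    tpm = TPM_TOTAL * rates / safe[None, :]
    tpm[:, empty] = 0.0
    return ExpressionMatrix(tpm, counts.gene_ids, counts.cell_ids, "TPM")


def log2_tpm(tpm: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(TPM + 1)."""
    if tpm.kind != "TPM":
        raise ValueError(f"expected a TPM matrix, got kind={tpm.kind!r}")
    return ExpressionMatrix(np.log2(tpm.values + 1.0), tpm.gene_ids, tpm.cell_ids, "log2tpm")


def count_detected(
    tpm: ExpressionMatrix,
    genes: Iterable[GeneRecord],
    biotype_filter: Sequence[str] | None = None,
    threshold: float = 1.0,
) -> tuple[np.ndarray, pd.Series]:
    """Per-cell detected-gene counts and per-gene dataset-level detection.

    A gene is detected in a cell iff TPM > ``threshold`` (strict); the
    per-gene flag is True iff the gene is detected in >= 1 cell.  When
    ``biotype_filter`` is given, only genes of those classes contribute.

    Returns
    -------
    (per_cell_counts, detected_flags)
        ``per_cell_counts``: int array over cells; ``detected_flags``:
        boolean Series indexed by the (filtered) gene ids.
    """
    if tpm.kind != "TPM":
        raise ValueError(f"expected a TPM matrix, got kind={tpm.kind!r}")
    index = genes_by_id(genes)
    if biotype_filter is not None:
        unknown = set(biotype_filter) - set(BIOTYPES)
        if unknown:
            raise ValueError(f"unknown biotype(s) in filter: {sorted(unknown)}")
        keep = [g for g in tpm.gene_ids if g in index and index[g].biotype in set(biotype_filter)]
    else:
        keep = [g for g in tpm.gene_ids if g in index]
    sub = tpm.subset_genes(keep)
    mask = sub.values > threshold
    per_cell = mask.sum(axis=0).astype(int)
    per_gene = pd.Series(mask.any(axis=1), index=keep, name="detected")
    return per_cell, per_gene


def detect_ratio(detected_total: int, annotated_total: int) -> float:
    """Percentage of annotated genes detected, rounded half-up to 2 decimals."""
    if annotated_total <= 0:
        raise ValueError("annotated_total must be positive")
    if not 0 <= detected_total <= annotated_total:
        raise ValueError("detected_total must be within [0, annotated_total]")
    pct = Decimal(100 * detected_total) / Decimal(annotated_total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def detection_summary(tpm: ExpressionMatrix, genes: Iterable[GeneRecord]) -> pd.DataFrame:
    """Per-biotype detection table: median (min-max) detected per cell,
    total detected, total annotated, detect ratio (%).

    Rows: coding, the 8 ncRNA classes, and an ``all_ncRNA`` aggregate.
    """
    genes = list(genes)
    index = genes_by_id(genes)
    annotated = pd.Series([g.biotype for g in genes]).value_counts()
    rows = []
    groups = [(b, (b,)) for b in BIOTYPES] + [("all_ncRNA", NCRNA_CLASSES)]
    for name, classes in groups:
        n_annot = int(annotated.reindex(list(classes)).fillna(0).sum())
        if n_annot == 0:
            continue
        per_cell, per_gene = count_detected(tpm, genes, biotype_filter=list(classes))
        rows.append(
            {
                "biotype": name,
                "median_per_cell": float(np.median(per_cell)) if len(per_cell) else 0.0,
                "min_per_cell": int(per_cell.min()) if len(per_cell) else 0,
                "max_per_cell": int(per_cell.max()) if len(per_cell) else 0,
                "genes_detected_total": int(per_gene.sum()),
                "genes_annotated": n_annot,
                "detect_ratio_pct": detect_ratio(int(per_gene.sum()), n_annot),
            }
        )
    return pd.DataFrame(rows)


def per_interval_detection_correlation(
    tpm: ExpressionMatrix,
    genes: Iterable[GeneRecord],
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Per time interval: Pearson R (and p) between per-cell detected
    protein-coding and detected ncRNA counts.

    ``annotation`` needs columns ``cell_id`` and ``time_interval``.
    Intervals with fewer than 3 cells are reported with a missing R and a
    reason rather than dropped.
    """
    from .coexpression import pearson_p, pearson_r

    genes = list(genes)
    coding_counts, _ = count_detected(tpm, genes, biotype_filter=["coding"])
    ncrna_counts, _ = count_detected(tpm, genes, biotype_filter=list(NCRNA_CLASSES))
    counts = pd.DataFrame(
        {"cell_id": tpm.cell_ids, "coding": coding_counts, "ncrna": ncrna_counts}
    ).merge(annotation[["cell_id", "time_interval"]], on="cell_id")
    rows = []
    for interval, grp in counts.groupby("time_interval", sort=False):
        n = len(grp)
        if n < 3:
            rows.append({"time_interval": interval, "r": np.nan, "p": np.nan,
                         "n_cells": n, "reason": "n<3"})
            continue
        r = pearson_r(grp["coding"].to_numpy(float), grp["ncrna"].to_numpy(float))
        if np.isnan(r):
            rows.append({"time_interval": interval, "r": np.nan, "p": np.nan,
                         "n_cells": n, "reason": "constant counts"})
            continue
        rows.append({"time_interval": interval, "r": r, "p": pearson_p(r, n),
                     "n_cells": n, "reason": ""})
    return pd.DataFrame(rows)
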