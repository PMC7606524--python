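"""Embryo-time staging of single cells against a bulk time course.

Each cell's log-scaled profile over the time-variable genes is Pearson-
correlated with every bulk reference column; a loess curve (span 0.75) is
fitted to correlation versus timepoint and evaluated on a 1-minute grid.
The grid argmax is the cell's continuous embryo time; the nearest reference
timepoint is the "most correlated bulk time point".  Cells whose best
correlation is weak (< 0.3) are flagged low-confidence, and constant
profiles are flagged rather than failing the batch.
"""

from __future__ import annotations

import bisect
import numpy as np
import pandas as pd

from .trends import loess_smoother_matrix
from .types import BulkTimeCourse, ExpressionMatrix, StagingResult

#: interval edges of the 10 embryo-time bins (minutes); bins are half-open
#: [lo, hi) with open ends below 150 and at/above 760
INTERVAL_EDGES = (150.0, 270.0, 330.0, 390.0, 450.0, 510.0, 580.0, 690.0, 760.0)

INTERVAL_LABELS = (
    "<150",
    "150–270",
    "270–330",
    "330–390",
    "390–450",
    "450–510",
    "510–580",
    "580–690",
    "690–760",
    ">760",
)


def bin_time_interval(t: float) -> str:
    """Map an embryo time (minutes) to one of the 10 interval labels."""
    if not np.isfinite(t) or t <= 0:
        raise ValueError(f"embryo time must be a positive number, got {t}")
    return INTERVAL_LABELS[bisect.bisect_right(INTERVAL_EDGES, t)]


def _staging_grid(bulk: BulkTimeCourse, step: float = 1.0) -> np.ndarray:
    t0, t1 = bulk.timepoints_min[0], bulk.timepoints_min[-1]
    return np.arange(t0, t1 + step / 2, step)


def stage_cell(
    cell_profile: pd.Series,
    bulk: BulkTimeCourse,
    span: float = 0.75,
    low_confidence_r: float = 0.3,
    cell_id: str = "cell",
) -> StagingResult:
    """Stage a single cell; ``cell_profile`` is log-scaled expression
    indexed by gene id (must cover the bulk time-variable genes)."""
    profile = cell_profile.reindex(bulk.time_variable_genes)
    if profile.isna().any():
        missing = profile.index[profile.isna()][:3].tolist()
        raise KeyError(f"cell profile missing time-variable genes, e.g. {missing}")
    matrix = ExpressionMatrix(
        profile.to_numpy(float)[:, None], bulk.time_variable_genes, [cell_id], "log2tpm",
        _validate=False,
    )
    return stage_cells(matrix, bulk, span=span, low_confidence_r=low_confidence_r)[0]


def stage_cells(
    log2tpm: ExpressionMatrix,
    bulk: BulkTimeCourse,
    span: float = 0.75,
    low_confidence_r: float = 0.3,
    grid_step_min: float = 1.0,
) -> list[StagingResult]:
    """Stage every cell of a log-scaled matrix against the bulk reference."""
    if len(bulk.timepoints_min) < 3:
        raise ValueError("staging requires at least 3 bulk timepoints")
    gene_index = {g: i for i, g in enumerate(log2tpm.gene_ids)}
    missing = [g for g in bulk.time_variable_genes if g not in gene_index]
    if missing:
        raise KeyError(f"matrix lacks time-variable gene(s), e.g. {missing[:3]}")
    idx = [gene_index[g] for g in bulk.time_variable_genes]
    X = log2tpm.values[idx]  # time-variable genes x cells
    B = bulk.time_variable_submatrix()  # time-variable genes x timepoints

    Bc = B - B.mean(axis=0, keepdims=True)
    Bn = np.linalg.norm(Bc, axis=0)
    if np.any(Bn == 0):
        raise ValueError("bulk column constant over the time-variable genes")
    Xc = X - X.mean(axis=0, keepdims=True)
    Xn = np.linalg.norm(Xc, axis=0)
    constant = Xn == 0
    Xn_safe = np.where(constant, 1.0, Xn)
    R = (Bc / Bn).T @ (Xc / Xn_safe[None, :])  # timepoints x cells
    R = np.clip(R, -1.0, 1.0)

    grid = _staging_grid(bulk, grid_step_min)
    # a quadratic is saturated at 3 reference timepoints; cap the degree
    degree = min(2, len(bulk.timepoints_min) - 2)
    L = loess_smoother_matrix(bulk.timepoints_min, grid, span=span, degree=degree)
    fitted = L @ R  # grid x cells
    best = np.argmax(fitted, axis=0)

    results = []
    for j, cell_id in enumerate(log2tpm.cell_ids):
        if constant[j]:
            results.append(
                StagingResult(
                    cell_id=cell_id,
                    correlations=np.full(len(bulk.timepoints_min), np.nan),
                    embryo_time_min=float("nan"),
                    assigned_bulk_timepoint=float("nan"),
                    max_r=float("nan"),
                    low_confidence=True,
                    reason="constant profile",
                )
            )
            continue
        t_hat = float(grid[best[j]])
        nearest = float(
            bulk.timepoints_min[np.argmin(np.abs(bulk.timepoints_min - t_hat))]
        )
        max_r = float(R[:, j].max())
        results.append(
            StagingResult(
                cell_id=cell_id,
                correlations=R[:, j].copy(),
                embryo_time_min=t_hat,
                assigned_bulk_timepoint=nearest,
                max_r=max_r,
                low_confidence=max_r < low_confidence_r,
                reason="low max correlation" if max_r < low_confidence_r else "",
            )
        )
    return results


def staging_table(results: list[StagingResult]) -> pd.DataFrame:
    """Tabular form of staging results, with interval labels."""
    rows = []
    for r in results:
        interval = (
            bin_time_interval(r.embryo_time_min)
            if np.isfinite(r.embryo_time_min)
            else ""
        )
        rows.append(
            {
                "cell_id": r.cell_id,
                "embryo_time_min": r.embryo_time_min,
                "assigned_bulk_timepoint": r.assigned_bulk_timepoint,
                "max_R": r.max_r,
                "interval": interval,
                "low_confidence": r.low_confidence,
                "reason": r.reason,
            }
        )
    return pd.DataFrame(rows)
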