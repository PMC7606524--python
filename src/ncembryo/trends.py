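"""Loess smoothing along embryo time and monotone-decrease detection.

The loess here is the classic local polynomial regression: for each
evaluation point the ceil(span*n) nearest x-neighbors are taken, weighted by
the tricube kernel on distance scaled to the furthest neighbor, and a
weighted least-squares polynomial (degree 2 by default) is fitted.  Because
the fit is linear in y, smoothing many genes over a shared set of cell
times reduces to one smoother-matrix multiply.

"Continuously decreasing" genes are operationalized as: z-scored
log2(TPM+1), loess-smoothed over embryo times within a window, evaluated on
a 10-minute grid, pointwise non-increasing (tolerance eps) with a minimum
total decline in scaled units.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np

from .types import ExpressionMatrix, TrendFit

log = logging.getLogger(__name__)

#: ridge added to the normal equations to tame duplicate-x degeneracy
_RIDGE = 1e-10


def loess_smoother_matrix(
    x: np.ndarray, grid: np.ndarray, span: float, degree: int = 2
) -> np.ndarray:
    """Smoother matrix L with fitted(grid) = L @ y for loess on fixed x.

    Each row of L holds the weights that map observations to the local
    weighted-least-squares fit at one grid point.
    """
    x = np.asarray(x, dtype=float)
    grid = np.asarray(grid, dtype=float)
    n = x.size
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}, got {n}")
    q = max(int(math.ceil(span * n)), degree + 1)
    L = np.zeros((grid.size, n))
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        idx = np.argpartition(d, q - 1)[:q]
        dmax = d[idx].max()
        if dmax == 0:
            w = np.ones(q)
        else:
            w = (1.0 - np.clip(d[idx] / dmax, 0.0, 1.0) ** 3) ** 3
        # design centered at x0 so the intercept is the fitted value
        X = np.vander(x[idx] - x0, degree + 1, increasing=True)
        XtW = X.T * w
        A = XtW @ X + _RIDGE * np.eye(degree + 1)
        # h maps y[idx] -> fitted value at x0
        h = np.linalg.solve(A, XtW)[0]
        L[i, idx] = h
    return L


class LoessFit:
    """Callable loess fit: evaluates the local WLS fit at arbitrary points."""

    def __init__(self, x: np.ndarray, y: np.ndarray, span: float, degree: int = 2):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same length")
        self.span = float(span)
        self.degree = int(degree)
        # trigger parameter validation eagerly
        loess_smoother_matrix(self.x, self.x[:1], self.span, self.degree)

    def __call__(self, grid) -> np.ndarray:
        grid = np.atleast_1d(np.asarray(grid, dtype=float))
        L = loess_smoother_matrix(self.x, grid, self.span, self.degree)
        return L @ self.y


def loess_fit(x, y, span: float, degree: int = 2) -> LoessFit:
    """Fit loess to (x, y); returns a callable evaluated on any grid."""
    return LoessFit(x, y, span, degree)


def scale_per_gene(row: np.ndarray) -> np.ndarray:
    """Z-score one expression row (subtract mean, divide by SD)."""
    row = np.asarray(row, dtype=float)
    sd = row.std()
    if sd == 0:
        raise ValueError("constant row cannot be scaled")
    return (row - row.mean()) / sd


def detect_decreasing(
    log2tpm: ExpressionMatrix,
    embryo_times_min: np.ndarray,
    window_min: tuple[float, float] = (270.0, 830.0),
    span: float = 0.5,
    eps: float = 0.01,
    min_decline: float = 0.5,
    exclude: Sequence[str] = (),
    grid_step_min: float = 10.0,
    degree: int = 1,
) -> list[TrendFit]:
    """Find genes whose smoothed scaled expression declines monotonically
    over the time window.

    Parameters
    ----------
    log2tpm
        log2(TPM+1) matrix.
    embryo_times_min
        Estimated embryo time per cell, aligned with ``log2tpm.cell_ids``.
    window_min
        Time window (minutes); only cells staged inside it enter the fit.
    exclude
        Gene ids to skip (e.g. known maternally deposited transcripts).
    """
    if log2tpm.kind != "log2tpm":
        raise ValueError(f"expected a log2tpm matrix, got kind={log2tpm.kind!r}")
    t = np.asarray(embryo_times_min, dtype=float)
    if t.shape[0] != log2tpm.n_cells:
        raise ValueError("embryo_times_min length must match the number of cells")
    lo, hi = window_min
    in_window = (t >= lo) & (t <= hi) & np.isfinite(t)
    if in_window.sum() < 10:
        raise ValueError(
            f"only {int(in_window.sum())} staged cells inside window {window_min}; need >= 10"
        )
    tx = t[in_window]
    grid = np.arange(max(lo, tx.min()), min(hi, tx.max()) + 1e-9, grid_step_min)
    # local-linear smoothing: quadratic local fits amplify noise curvature
    # into spurious up-and-down wiggle, which a pointwise monotonicity gate
    # cannot tolerate; degree stays configurable
    L = loess_smoother_matrix(tx, grid, span=span, degree=degree)

    excluded = set(exclude)
    keep_idx, keep_ids = [], []
    n_constant = 0
    for i, g in enumerate(log2tpm.gene_ids):
        if g in excluded:
            continue
        row = log2tpm.values[i, in_window]
        if row.std() == 0:
            n_constant += 1
            continue
        keep_idx.append(i)
        keep_ids.append(g)
    if n_constant:
        log.info("skipped %d constant gene(s) in trend detection", n_constant)
    if not keep_idx:
        return []

    rows = log2tpm.values[np.asarray(keep_idx)][:, in_window]
    z = (rows - rows.mean(axis=1, keepdims=True)) / rows.std(axis=1, keepdims=True)
    fitted = z @ L.T  # genes x grid
    diffs = np.diff(fitted, axis=1)
    monotone = (diffs <= eps).all(axis=1)
    decline = fitted[:, 0] - fitted[:, -1]
    flagged = monotone & (decline >= min_decline)

    out = []
    for j in np.flatnonzero(flagged):
        out.append(
            TrendFit(
                gene_id=keep_ids[j],
                grid_times_min=grid.copy(),
                fitted=fitted[j].copy(),
                monotone_decreasing=True,
                total_decline=float(decline[j]),
            )
        )
    return out
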