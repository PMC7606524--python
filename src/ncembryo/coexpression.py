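"""ncRNA-coding co-expression screen (guilt by association).

All (ncRNA, coding) gene pairs are Pearson-correlated on log2(TPM+1) across
cells; pairs with |R| > 0.6 and p < 1e-5 (both strict) are kept, and an
ncRNA passes the hub rule when it has at least 4 positively co-expressed or
at least 4 negatively co-expressed coding partners — same-sign partners are
counted separately, never pooled.

P-values use the exact t transform of the correlation coefficient,
t = r*sqrt(n-2)/sqrt(1-r^2) with df = n-2.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    NCRNA_CLASSES,
    CoexpressionEdge,
    ExpressionMatrix,
    GeneRecord,
    NcRNAHub,
    genes_by_id,
)

log = logging.getLogger(__name__)


def pearson_r(x, y) -> float:
    """Sample Pearson correlation; NaN when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        return float("nan")
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def pearson_p(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation at sample size n (t transform)."""
    if n < 3:
        raise ValueError("need n >= 3")
    if np.isnan(r):
        return float("nan")
    if abs(r) > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows scaled so that Z_a @ Z_b gives Pearson r; flags constant rows."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    constant = norms == 0
    z = centered / np.where(constant, 1.0, norms)[:, None]
    return z, constant


def screen_pairs(
    log2tpm: ExpressionMatrix,
    genes: Iterable[GeneRecord],
    r_min: float = 0.6,
    p_max: float = 1e-5,
) -> list[CoexpressionEdge]:
    """All (ncRNA, coding) pairs passing |r| > r_min and p < p_max (strict)."""
    if log2tpm.kind != "log2tpm":
        raise ValueError(f"expected a log2tpm matrix, got kind={log2tpm.kind!r}")
    index = genes_by_id(genes)
    ncrna_ids = [g for g in log2tpm.gene_ids
                 if g in index and index[g].biotype in NCRNA_CLASSES]
    coding_ids = [g for g in log2tpm.gene_ids
                  if g in index and index[g].biotype == "coding"]
    if not ncrna_ids or not coding_ids:
        raise ValueError("screen requires at least one ncRNA and one coding gene")
    n = log2tpm.n_cells
    if n < 3:
        raise ValueError("screen requires at least 3 cells")

    Zn, const_n = _standardize_rows(log2tpm.subset_genes(ncrna_ids).values)
    Zc, const_c = _standardize_rows(log2tpm.subset_genes(coding_ids).values)
    n_const = int(const_n.sum() + const_c.sum())
    if n_const:
        log.info("skipped %d constant gene(s) in co-expression screen", n_const)

    R = np.clip(Zn @ Zc.T, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = np.abs(R) * np.sqrt(n - 2) / np.sqrt(np.maximum(1.0 - R * R, 0.0))
    P = 2.0 * stats.t.sf(t, df=n - 2)
    P[np.abs(R) >= 1.0] = 0.0

    valid = ~const_n[:, None] & ~const_c[None, :]
    hits = valid & (np.abs(R) > r_min) & (P < p_max)
    edges = [
        CoexpressionEdge(
            ncrna_id=ncrna_ids[i],
            coding_id=coding_ids[j],
            r=float(R[i, j]),
            p=float(P[i, j]),
            sign="pos" if R[i, j] > 0 else "neg",
        )
        for i, j in zip(*np.nonzero(hits))
    ]
    edges.sort(key=lambda e: (e.ncrna_id, e.coding_id))
    return edges


def select_hubs(
    edges: Sequence[CoexpressionEdge],
    min_partners: int = 4,
    partner_p_max: float = 1e-5,
) -> list[NcRNAHub]:
    """Apply the >= ``min_partners`` same-sign partner rule per ncRNA.

    Positive and negative partners are tallied separately; an ncRNA passes
    when either tally reaches ``min_partners``.
    """
    by_ncrna: dict[str, list[CoexpressionEdge]] = {}
    for e in edges:
        by_ncrna.setdefault(e.ncrna_id, []).append(e)
    hubs = []
    for ncrna_id in sorted(by_ncrna):
        es = [e for e in by_ncrna[ncrna_id] if e.p < partner_p_max]
        n_pos = sum(e.sign == "pos" for e in es)
        n_neg = sum(e.sign == "neg" for e in es)
        hubs.append(
            NcRNAHub(
                ncrna_id=ncrna_id,
                n_pos_partners=n_pos,
                n_neg_partners=n_neg,
                passes=n_pos >= min_partners or n_neg >= min_partners,
                partner_ids=sorted(e.coding_id for e in es),
            )
        )
    return hubs


def hub_report(
    hubs: Sequence[NcRNAHub],
    edges: Sequence[CoexpressionEdge],
    expression: ExpressionMatrix | None = None,
    cluster_labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tabulate passing hubs sorted by total partner count.

    Coding genes linked to different ncRNAs with opposite signs are listed
    in the ``opposite_pairs`` column.  When an expression matrix and
    per-cell cluster labels are given, the hub ncRNA's mean expression per
    cluster is appended.
    """
    sign_by_gene: dict[str, set[str]] = {}
    for e in edges:
        sign_by_gene.setdefault(e.coding_id, set()).add(e.sign)
    double_signed = {g for g, signs in sign_by_gene.items() if len(signs) > 1}

    rows = []
    for hub in sorted(
        hubs, key=lambda h: (-(h.n_pos_partners + h.n_neg_partners), h.ncrna_id)
    ):
        if not hub.passes:
            continue
        row = {
            "ncrna_id": hub.ncrna_id,
            "n_pos_partners": hub.n_pos_partners,
            "n_neg_partners": hub.n_neg_partners,
            "passes": hub.passes,
            "partners": ";".join(hub.partner_ids),
            "opposite_pairs": ";".join(
                sorted(set(hub.partner_ids) & double_signed)
            ),
        }
        if expression is not None and cluster_labels is not None:
            values = expression.gene_row(hub.ncrna_id)
            for k in np.unique(cluster_labels):
                row[f"mean_expr_cluster_{k}"] = float(
                    values[np.asarray(cluster_labels) == k].mean()
                )
        rows.append(row)
    return pd.DataFrame(rows)


def edges_table(edges: Sequence[CoexpressionEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"ncrna_id": e.ncrna_id, "coding_id": e.coding_id, "r": e.r,
             "p": e.p, "sign": e.sign}
            for e in edges
        ],
        columns=["ncrna_id", "coding_id", "r", "p", "sign"],
    )
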