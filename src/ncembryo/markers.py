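"""Cluster-specific marker detection.

A gene is reported as a marker of a cluster when it is expressed
(normalized value > 0) in at least ``min_pct`` of the cluster's cells and
its natural-log fold change — computed on back-transformed means with a
pseudocount of 1 — exceeds ``ln_fc_min``.  Significance comes from a
two-sided Wilcoxon rank-sum test (normal approximation with tie and
continuity corrections) and Bonferroni adjustment over all genes tested.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .types import ExpressionMatrix, MarkerRecord


def wilcoxon_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p via the normal approximation with tie
    and continuity corrections (the R ``wilcox.test`` convention)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0  # all values tied
    z = (w - mu - 0.5 * np.sign(w - mu)) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def log_fold_change(x_in: np.ndarray, x_out: np.ndarray) -> float:
    """ln fold change on back-transformed means with pseudocount 1:
    ln(mean(e^x - 1) + 1) in-cluster minus the same outside."""
    m_in = np.expm1(np.asarray(x_in, dtype=float)).mean()
    m_out = np.expm1(np.asarray(x_out, dtype=float)).mean()
    return float(np.log1p(m_in) - np.log1p(m_out))


def find_markers(
    norm: ExpressionMatrix,
    labels,
    cluster,
    min_pct: float = 0.75,
    ln_fc_min: float = 0.25,
) -> list[MarkerRecord]:
    """Markers of one cluster versus all other cells.

    Returns only genes passing both gates (pct_in >= min_pct and
    ln_fc > ln_fc_min), with Bonferroni-adjusted p over all genes in the
    matrix.
    """
    if norm.kind != "lognorm":
        raise ValueError(f"expected a lognorm matrix, got kind={norm.kind!r}")
    labels = np.asarray(labels)
    if labels.shape[0] != norm.n_cells:
        raise ValueError("labels must align with the matrix cells")
    in_mask = labels == cluster
    if not in_mask.any():
        raise ValueError(f"cluster {cluster!r} not present in labels")
    if in_mask.sum() < 3 or (~in_mask).sum() < 3:
        raise ValueError("need at least 3 cells inside and outside the cluster")

    X = norm.values
    n_genes_total = norm.n_genes
    pct_in = (X[:, in_mask] > 0).mean(axis=1)
    pct_out = (X[:, ~in_mask] > 0).mean(axis=1)
    mean_in = np.expm1(X[:, in_mask]).mean(axis=1)
    mean_out = np.expm1(X[:, ~in_mask]).mean(axis=1)
    ln_fc = np.log1p(mean_in) - np.log1p(mean_out)

    out = []
    for i in np.flatnonzero((pct_in >= min_pct) & (ln_fc > ln_fc_min)):
        p = wilcoxon_rank_sum_p(X[i, in_mask], X[i, ~in_mask])
        out.append(
            MarkerRecord(
                gene_id=norm.gene_ids[i],
                cluster=cluster,
                ln_fc=float(ln_fc[i]),
                pct_in=float(pct_in[i]),
                pct_out=float(pct_out[i]),
                p=p,
                p_adj=min(1.0, p * n_genes_total),
            )
        )
    return out


def find_all_markers(
    norm: ExpressionMatrix,
    labels,
    min_pct: float = 0.75,
    ln_fc_min: float = 0.25,
) -> list[MarkerRecord]:
    """Run :func:`find_markers` for every cluster with enough cells."""
    labels = np.asarray(labels)
    records = []
    for cluster in np.unique(labels):
        if (labels == cluster).sum() < 3 or (labels != cluster).sum() < 3:
            continue
        records.extend(find_markers(norm, labels, cluster, min_pct, ln_fc_min))
    return records


def top_markers(records: list[MarkerRecord], k: int = 10) -> list[MarkerRecord]:
    """Top-k markers of one cluster: p_adj < 0.05, sorted by ln_fc
    descending, ties broken lexicographically by gene id."""
    if records and len({r.cluster for r in records}) > 1:
        raise ValueError("top_markers expects records from a single cluster")
    passing = [r for r in records if r.p_adj < 0.05]
    passing.sort(key=lambda r: (-r.ln_fc, r.gene_id))
    return passing[:k]
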