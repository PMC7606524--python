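"""Normalization, PCA, graph clustering and partition comparison.

The workflow mirrors the standard single-cell recipe: per-cell
log-normalization (scale factor 10,000, natural log), per-gene
standardization with clipping, PCA on all genes (top 20 PCs), a shared
nearest-neighbor graph (k = 20, Euclidean in PC space) and modularity
community detection (Leiden, resolution 1.0).  Cells can be clustered on
the combined gene set, protein-coding genes only, or ncRNAs only, and the
resulting partitions compared by contingency, adjusted Rand index and
per-cluster dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import igraph
import leidenalg
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .types import NCRNA_CLASSES, ClusterComparison, ExpressionMatrix, GeneRecord, genes_by_id


@dataclass
class ClusteringConfig:
    scale_factor: float = 10_000.0
    n_pcs: int = 20
    resolution: float = 1.0
    feature_set: str = "combined"  # combined | coding | ncrna
    clip_value: float = 10.0
    knn_k: int = 20
    snn_prune: float = 0.0  # Jaccard weights already damp weak links
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pcs < 2:
            raise ValueError("n_pcs must be >= 2")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.feature_set not in ("combined", "coding", "ncrna"):
            raise ValueError(f"unknown feature_set {self.feature_set!r}")


def log_normalize(counts: ExpressionMatrix, scale_factor: float = 10_000.0) -> ExpressionMatrix:
    """Per cell: ln(1 + scale_factor * count / total_counts)."""
    if counts.kind != "counts":
        raise ValueError(f"expected a counts matrix, got kind={counts.kind!r}")
    totals = counts.values.sum(axis=0)
    zero = totals == 0
    if zero.any():
        bad = [c for c, z in zip(counts.cell_ids, zero) if z]
        raise ValueError(f"cells with zero total counts: {bad[:10]}")
    norm = np.log1p(scale_factor * counts.values / totals[None, :])
    return ExpressionMatrix(norm, counts.gene_ids, counts.cell_ids, "lognorm")


def pca_embed(norm: ExpressionMatrix, config: ClusteringConfig) -> np.ndarray:
    """Cells x n_pcs coordinates after gene standardization and clipping.

    Genes are centered and scaled to unit variance across cells,
    zero-variance genes dropped, values clipped at +/- clip_value, then PCA
    (full SVD).  Component signs are fixed so each component's
    largest-magnitude gene loading is positive.
    """
    if norm.n_cells < config.n_pcs + 1:
        raise ValueError(
            f"need at least n_pcs+1={config.n_pcs + 1} cells, got {norm.n_cells}"
        )
    X = norm.values  # genes x cells
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    if keep.sum() < config.n_pcs:
        raise ValueError(
            f"only {int(keep.sum())} non-constant genes; need >= n_pcs={config.n_pcs}"
        )
    Z = (X[keep] - mu[keep]) / sd[keep]
    np.clip(Z, -config.clip_value, config.clip_value, out=Z)
    pca = PCA(n_components=config.n_pcs, svd_solver="full")
    coords = pca.fit_transform(Z.T)  # cells x n_pcs
    # deterministic sign convention
    for k in range(config.n_pcs):
        loading = pca.components_[k]
        j = int(np.argmax(np.abs(loading)))
        if loading[j] < 0:
            coords[:, k] *= -1.0
    return coords


def _snn_graph(embedding: np.ndarray, k: int, prune: float) -> igraph.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Every pair of cells sharing at least one of their k nearest neighbors
    (self included) is a candidate edge; the weight is the Jaccard overlap
    of the two neighbor sets, pruned below ``prune``.
    """
    import scipy.sparse as sp

    n = embedding.shape[0]
    nn = NearestNeighbors(n_neighbors=k, algorithm="brute").fit(embedding)
    _, idx = nn.kneighbors(embedding)  # includes self; ties broken by index
    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix(
        (np.ones(n * k), (rows, idx.ravel())), shape=(n, n), dtype=float
    )
    shared = (A @ A.T).tocoo()  # pairwise shared-neighbor counts
    mask = shared.row < shared.col
    r, c, s = shared.row[mask], shared.col[mask], shared.data[mask]
    w = s / (2 * k - s)  # Jaccard: |A&B| / |A|B union|
    keep = w >= prune
    g = igraph.Graph(n=n, edges=list(zip(r[keep], c[keep])))
    g.es["weight"] = w[keep]
    return g


def cluster_cells(embedding: np.ndarray, config: ClusteringConfig) -> np.ndarray:
    """Graph clustering of cells in PC space; labels 0..K-1 by decreasing
    cluster size, deterministic given the config seed."""
    embedding = np.asarray(embedding, dtype=float)
    if not np.all(np.isfinite(embedding)):
        raise ValueError("embedding contains non-finite values")
    n = embedding.shape[0]
    if n < config.knn_k:
        raise ValueError(
            f"{n} cells is fewer than knn_k={config.knn_k}; lower knn_k"
        )
    # canonical cell order makes the labeling invariant to input order
    order = np.lexsort(embedding.T[::-1])
    embedding = embedding[order]
    g = _snn_graph(embedding, config.knn_k, config.snn_prune)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if g.ecount() else None,
        resolution_parameter=config.resolution,
        seed=config.seed,
        n_iterations=-1,
    )
    raw = np.asarray(part.membership)
    # relabel by decreasing size; ties broken by smallest canonical index
    by_size = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), int(np.flatnonzero(raw == c)[0])),
    )
    remap = {c: i for i, c in enumerate(by_size)}
    labels = np.empty(n, dtype=int)
    labels[order] = [remap[c] for c in raw]
    return labels


def embed_2d(embedding: np.ndarray, seed: int = 0) -> np.ndarray:
    """2-D UMAP of the PC coordinates; for visualization only."""
    embedding = np.asarray(embedding, dtype=float)
    if embedding.shape[0] < 10:
        raise ValueError("need at least 10 cells for a 2-D embedding")
    import umap

    reducer = umap.UMAP(n_components=2, random_state=seed)
    return np.asarray(reducer.fit_transform(embedding), dtype=float)


def compare_partitions(labels_a, labels_b) -> ClusterComparison:
    """Contingency, adjusted Rand index and per-cluster dispersion (how many
    clusters of B each cluster of A spreads over)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must cover the same cells")
    contingency = pd.crosstab(pd.Series(a, name="a"), pd.Series(b, name="b"))
    dispersion = {
        int(c): int((contingency.loc[c] > 0).sum()) for c in contingency.index
    }
    return ClusterComparison(
        contingency=contingency,
        adjusted_rand_index=float(adjusted_rand_score(a, b)),
        dispersion=dispersion,
    )


def subset_by_feature_set(
    counts: ExpressionMatrix, genes: Iterable[GeneRecord], feature_set: str
) -> ExpressionMatrix:
    """Restrict a matrix to combined / coding / ncRNA features."""
    index = genes_by_id(genes)
    if feature_set == "combined":
        keep = [g for g in counts.gene_ids if g in index]
    elif feature_set == "coding":
        keep = [g for g in counts.gene_ids if g in index and index[g].biotype == "coding"]
    elif feature_set == "ncrna":
        keep = [
            g for g in counts.gene_ids
            if g in index and index[g].biotype in NCRNA_CLASSES
        ]
    else:
        raise ValueError(f"unknown feature_set {feature_set!r}")
    if not keep:
        raise ValueError(f"feature set {feature_set!r} selects no genes")
    return counts.subset_genes(keep)


def run_feature_set_clustering(
    counts: ExpressionMatrix,
    genes: Iterable[GeneRecord],
    feature_set: str,
    config: ClusteringConfig | None = None,
) -> np.ndarray:
    """Log-normalize, embed and cluster cells on one feature subset with the
    same clustering parameters."""
    config = config or ClusteringConfig()
    genes = list(genes)
    sub = subset_by_feature_set(counts, genes, feature_set)
    norm = log_normalize(sub, config.scale_factor)
    coords = pca_embed(norm, config)
    return cluster_cells(coords, config)
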