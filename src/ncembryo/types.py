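"""Shared domain types for the ncembryo pipeline.

The central containers are deliberately thin: an expression matrix is a dense
genes x cells float array with axis labels and a tag saying what the values
are (raw counts, TPM, log2(TPM+1) or log-normalized counts), a bulk time
course is a genes x timepoints log-scale matrix with the list of
time-variable genes used for staging, and gene annotation is a set of
:class:`GeneRecord` partitioning genes into protein-coding plus eight ncRNA
classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: protein-coding plus the eight ncRNA annotation classes
BIOTYPES = (
    "coding",
    "antisense",
    "lincRNA",
    "rRNA",
    "snoRNA",
    "pseudogene",
    "snRNA",
    "tRNA",
    "unknown_ncRNA",
)

#: the eight non-coding classes (everything except ``coding``)
NCRNA_CLASSES = tuple(b for b in BIOTYPES if b != "coding")

#: allowed value kinds for :class:`ExpressionMatrix`
MATRIX_KINDS = ("counts", "TPM", "log2tpm", "lognorm")

TPM_TOTAL = 1e6


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: identifier, biotype class and transcript length.

    ``length_bp`` is the exonic length of the longest transcript (used for
    TPM); it defaults to 1000 bp when the annotation source carries no
    length information.
    """

    gene_id: str
    biotype: str
    length_bp: int = 1000

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(
                f"unknown biotype {self.biotype!r} for gene {self.gene_id!r}; "
                f"expected one of {BIOTYPES}"
            )
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if int(self.length_bp) < 1:
            raise ValueError(
                f"length_bp must be >= 1 for gene {self.gene_id!r}, got {self.length_bp}"
            )

    @property
    def is_coding(self) -> bool:
        return self.biotype == "coding"


def genes_by_id(genes: Iterable[GeneRecord]) -> dict[str, GeneRecord]:
    """Index records by gene_id, rejecting duplicates."""
    out: dict[str, GeneRecord] = {}
    for g in genes:
        if g.gene_id in out:
            raise ValueError(f"duplicate gene_id {g.gene_id!r} in annotation set")
        out[g.gene_id] = g
    return out


class ExpressionMatrix:
    """Dense genes x cells expression values with axis labels and a kind tag.

    Invariants enforced at construction: unique gene and cell identifiers,
    no negative entries, and for ``kind='TPM'`` every non-empty cell column
    sums to 1e6 within relative tolerance.
    """

    def __init__(
        self,
        values: np.ndarray,
        gene_ids: Sequence[str],
        cell_ids: Sequence[str],
        kind: str,
        *,
        _validate: bool = True,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        gene_ids = list(map(str, gene_ids))
        cell_ids = list(map(str, cell_ids))
        if values.shape != (len(gene_ids), len(cell_ids)):
            raise ValueError(
                f"shape mismatch: values {values.shape} vs "
                f"{len(gene_ids)} genes x {len(cell_ids)} cells"
            )
        if kind not in MATRIX_KINDS:
            raise ValueError(f"kind must be one of {MATRIX_KINDS}, got {kind!r}")
        if _validate:
            if len(set(gene_ids)) != len(gene_ids):
                raise ValueError("duplicated gene_ids")
            if len(set(cell_ids)) != len(cell_ids):
                raise ValueError("duplicated cell_ids")
            if values.size and values.min() < 0:
                raise ValueError("negative expression values are not allowed")
            if kind == "TPM" and values.size:
                sums = values.sum(axis=0)
                nonzero = sums > 0
                if not np.allclose(sums[nonzero], TPM_TOTAL, rtol=1e-6):
                    raise ValueError("TPM columns must sum to 1e6")
        self.values = values
        self.gene_ids = gene_ids
        self.cell_ids = cell_ids
        self.kind = kind
        self._gene_index = {g: i for i, g in enumerate(gene_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_row(self, gene_id: str) -> np.ndarray:
        return self.values[self._gene_index[gene_id]]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self._gene_index[g] for g in gene_ids]
        return ExpressionMatrix(
            self.values[idx], list(gene_ids), self.cell_ids, self.kind, _validate=False
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and np.array_equal(self.values, other.values)
        )

    def allclose(self, other: "ExpressionMatrix", rtol: float = 1e-9) -> bool:
        return (
            self.kind == other.kind
            and self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and np.allclose(self.values, other.values, rtol=rtol, atol=0)
        )

    def __repr__(self) -> str:
        return (
            f"ExpressionMatrix(kind={self.kind!r}, "
            f"n_genes={self.n_genes}, n_cells={self.n_cells})"
        )


@dataclass
class BulkTimeCourse:
    """Genes x reference timepoints (minutes) log-scale expression, plus the
    time-variable gene list used for correlation staging."""

    gene_ids: list[str]
    timepoints_min: np.ndarray
    values: np.ndarray
    time_variable_genes: list[str]

    def __post_init__(self) -> None:
        self.timepoints_min = np.asarray(self.timepoints_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timepoints_min) < 3:
            raise ValueError("a bulk time course needs at least 3 timepoints")
        if np.any(np.diff(self.timepoints_min) <= 0) or self.timepoints_min[0] <= 0:
            raise ValueError("timepoints_min must be strictly increasing positive")
        if self.values.shape != (len(self.gene_ids), len(self.timepoints_min)):
            raise ValueError("bulk values shape mismatch")
        if not self.time_variable_genes:
            raise ValueError("time_variable_genes must be non-empty")
        missing = set(self.time_variable_genes) - set(self.gene_ids)
        if missing:
            raise ValueError(f"time_variable_genes not in gene_ids: {sorted(missing)[:5]}")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    def column(self, timepoint: float) -> np.ndarray:
        j = int(np.argmin(np.abs(self.timepoints_min - timepoint)))
        return self.values[:, j]

    def time_variable_submatrix(self) -> np.ndarray:
        idx = [self._gene_index[g] for g in self.time_variable_genes]
        return self.values[idx]


@dataclass
class CellAnnotation:
    """Per-cell metadata accumulated along the pipeline."""

    cell_id: str
    embryo_time_min: float | None = None
    time_interval: str | None = None
    cluster_combined: int | None = None
    cluster_coding: int | None = None
    cluster_ncrna: int | None = None


@dataclass(frozen=True)
class CoexpressionEdge:
    """One retained ncRNA-coding gene pair from the co-expression screen."""

    ncrna_id: str
    coding_id: str
    r: float
    p: float
    sign: str  # "pos" | "neg"

    def __post_init__(self) -> None:
        if self.sign not in ("pos", "neg"):
            raise ValueError(f"sign must be 'pos' or 'neg', got {self.sign!r}")


@dataclass
class NcRNAHub:
    """An ncRNA with its same-sign partner tallies and the >=4-partner flag."""

    ncrna_id: str
    n_pos_partners: int
    n_neg_partners: int
    passes: bool
    partner_ids: list[str] = field(default_factory=list)


@dataclass
class MarkerRecord:
    """One cluster-specific marker candidate."""

    gene_id: str
    cluster: int
    ln_fc: float
    pct_in: float
    pct_out: float
    p: float
    p_adj: float


@dataclass
class StagingResult:
    """Embryo-time assignment for one cell."""

    cell_id: str
    correlations: np.ndarray
    embryo_time_min: float
    assigned_bulk_timepoint: float
    max_r: float
    low_confidence: bool
    reason: str = ""


@dataclass
class ClusterComparison:
    """Contingency, adjusted Rand index and per-cluster dispersion between
    two labelings of the same cells."""

    contingency: pd.DataFrame
    adjusted_rand_index: float
    dispersion: dict


@dataclass
class TrendFit:
    """A loess-smoothed temporal profile for one gene (scaled log2-TPM)."""

    gene_id: str
    grid_times_min: np.ndarray
    fitted: np.ndarray
    monotone_decreasing: bool
    total_decline: float


@dataclass
class HubSpec:
    """Planted hub: one ncRNA driving a set of coding partners."""

    ncrna_id: str
    partner_ids: list[str]
    sign: str  # "pos" | "neg"


@dataclass
class SyntheticTruth:
    """Ground truth planted by the synthetic generator, for recovery tests."""

    cell_ids: list[str]
    cell_types: list[str]
    embryo_time_min: np.ndarray
    hubs: list[HubSpec]
    markers: dict  # cell type -> list of marker gene ids
    trend_genes: dict  # gene id -> decline amplitude (log2 units)
    time_variable_genes: list[str]
    ncrna_only_type: str | None
    disguise_types: dict  # cell id -> coding-profile disguise (ncrna_only cells)
    bulk: BulkTimeCourse | None = None
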