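"""Readers and writers for the delimited-text and Matrix-Market formats the
pipeline touches.

Annotation can come from Ensembl-style GTF/GFF3 (``gene_biotype``/``biotype``
attributes) or from a plain two-column gene -> biotype table with an optional
third length column.  Expression matrices round-trip through TSV (genes as
rows, cells as columns) or Matrix-Market triplets with ``genes.tsv`` /
``cells.tsv`` side files.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import BIOTYPES, ExpressionMatrix, GeneRecord

log = logging.getLogger(__name__)

#: annotation biotype vocabulary -> the nine internal classes.  Anything not
#: listed here and not flagged as coding falls into ``unknown_ncRNA``,
#: mirroring the "ncRNAs of unknown types" bucket.
BIOTYPE_MAP = {
    "protein_coding": "coding",
    "coding": "coding",
    "antisense": "antisense",
    "antisense_RNA": "antisense",
    "lincRNA": "lincRNA",
    "lncRNA": "lincRNA",
    "rRNA": "rRNA",
    "snoRNA": "snoRNA",
    "snRNA": "snRNA",
    "tRNA": "tRNA",
    "pseudogene": "pseudogene",
    "processed_pseudogene": "pseudogene",
    "unprocessed_pseudogene": "pseudogene",
    "ncRNA": "unknown_ncRNA",
    "unknown_ncRNA": "unknown_ncRNA",
}


def map_biotype(raw: str) -> str:
    """Map an annotation biotype string to one of the nine classes."""
    raw = raw.strip()
    if raw in BIOTYPE_MAP:
        return BIOTYPE_MAP[raw]
    if raw in BIOTYPES:
        return raw
    if raw.endswith("_pseudogene"):
        return "pseudogene"
    return "unknown_ncRNA"


# ---------------------------------------------------------------------------
# annotation


def _validate_gff_lines(path: str | Path) -> None:
    """Raise a line-numbered error for structurally broken GTF/GFF3 lines."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise ValueError(
                    f"{path}: line {lineno}: invalid coordinate range {start}-{end}"
                )


def _read_annotation_gff(path: str | Path, fmt: str) -> set[GeneRecord]:
    import gffutils

    _validate_gff_lines(path)
    if os.path.getsize(path) == 0 or not any(
        line.strip() and not line.startswith("#") for line in open(path)
    ):
        log.warning("annotation file %s is empty; returning no genes", path)
        return set()
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="merge",
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            force_gff=(fmt == "gff3"),
        )
    except Exception as exc:  # pragma: no cover - gffutils error paths vary
        raise ValueError(f"failed to parse {path} as {fmt}: {exc}") from exc

    records: set[GeneRecord] = set()
    for gene in db.features_of_type("gene"):
        attrs = gene.attributes
        gene_id = (attrs.get("gene_id") or attrs.get("ID") or [gene.id])[0]
        gene_id = gene_id.removeprefix("gene:")
        raw_biotypes = attrs.get("gene_biotype") or attrs.get("biotype") or []
        mapped = sorted({map_biotype(b) for b in raw_biotypes}) or ["unknown_ncRNA"]
        if len(mapped) > 1:
            raise ValueError(
                f"duplicate gene_id {gene_id!r} with conflicting biotypes {mapped}"
            )
        # longest-transcript exonic length; fall back to gene-level exons,
        # then to the gene span
        transcript_lengths = []
        for tx in db.children(gene, level=1):
            if tx.featuretype == "exon":
                continue
            exon_total = sum(
                e.end - e.start + 1 for e in db.children(tx, featuretype="exon")
            )
            if exon_total:
                transcript_lengths.append(exon_total)
        if not transcript_lengths:
            exon_total = sum(
                e.end - e.start + 1 for e in db.children(gene, featuretype="exon")
            )
            transcript_lengths.append(exon_total or gene.end - gene.start + 1)
        records.add(
            GeneRecord(gene_id=gene_id, biotype=mapped[0], length_bp=max(transcript_lengths))
        )
    if not records:
        log.warning("no gene features found in %s", path)
    return records


def _read_annotation_tsv(path: str | Path) -> set[GeneRecord]:
    records: dict[str, GeneRecord] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected at least 2 tab-separated "
                    f"columns (gene_id, biotype)"
                )
            gene_id = fields[0].strip()
            biotype = map_biotype(fields[1])
            if len(fields) >= 3 and fields[2].strip():
                try:
                    length = int(fields[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: line {lineno}: non-integer length {fields[2]!r}"
                    ) from exc
            else:
                length = 1000
            if gene_id in records:
                if records[gene_id].biotype != biotype:
                    raise ValueError(
                        f"{path}: line {lineno}: duplicate gene_id {gene_id!r} "
                        f"with conflicting biotype"
                    )
                continue
            records[gene_id] = GeneRecord(gene_id=gene_id, biotype=biotype, length_bp=length)
    if not records:
        log.warning("annotation file %s is empty; returning no genes", path)
    return set(records.values())


def read_annotation(path: str | Path, format: str = "two_column_tsv") -> set[GeneRecord]:
    """Read gene annotation into a set of :class:`GeneRecord`.

    Parameters
    ----------
    path
        Annotation file.
    format
        One of ``gtf``, ``gff3``, ``two_column_tsv``.  The TSV form is
        ``gene_id <tab> biotype [<tab> length_bp]`` with no header; lines
        starting with ``#`` are ignored.
    """
    if format in ("gtf", "gff3"):
        return _read_annotation_gff(path, format)
    if format == "two_column_tsv":
        return _read_annotation_tsv(path)
    raise ValueError(f"unknown annotation format {format!r}")


def write_annotation(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write annotation as the two-column TSV dialect (with length column)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: g.gene_id):
            fh.write(f"{g.gene_id}\t{g.biotype}\t{g.length_bp}\n")


# ---------------------------------------------------------------------------
# expression matrices


def read_matrix(
    path: str | Path,
    format: str = "tsv",
    kind: str = "counts",
    genes_file: str | Path | None = None,
    cells_file: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes x cells expression matrix.

    ``tsv``: first column gene ids, header row cell ids.
    ``matrix_market_triplet``: Matrix-Market coordinate file with side files
    ``genes.tsv`` / ``cells.tsv`` (one identifier per line) next to it unless
    given explicitly; entries absent from the triplet list are zero.
    """
    path = Path(path)
    if format == "tsv":
        header = open(path).readline().rstrip("\n").split("\t")[1:]
        if len(set(header)) != len(header):
            raise ValueError(f"{path}: duplicated gene or cell identifiers")
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValueError(f"{path}: duplicated gene or cell identifiers")
        values = df.to_numpy(dtype=float)
        if values.size and values.min() < 0:
            raise ValueError(f"{path}: negative expression value")
        return ExpressionMatrix(values, list(df.index.astype(str)), list(df.columns.astype(str)), kind)
    if format == "matrix_market_triplet":
        genes_file = Path(genes_file) if genes_file else path.parent / "genes.tsv"
        cells_file = Path(cells_file) if cells_file else path.parent / "cells.tsv"
        gene_ids = [l.strip().split("\t")[0] for l in open(genes_file) if l.strip()]
        cell_ids = [l.strip().split("\t")[0] for l in open(cells_file) if l.strip()]
        mat = scipy.io.mmread(str(path))
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        if values.shape != (len(gene_ids), len(cell_ids)):
            raise ValueError(
                f"{path}: matrix shape {values.shape} does not match side files "
                f"({len(gene_ids)} genes, {len(cell_ids)} cells)"
            )
        if values.size and values.min() < 0:
            raise ValueError(f"{path}: negative expression value")
        return ExpressionMatrix(values, gene_ids, cell_ids, kind)
    raise ValueError(f"unknown matrix format {format!r}")


def write_matrix(
    matrix: ExpressionMatrix, path: str | Path, format: str = "tsv"
) -> None:
    """Write a matrix as TSV or Matrix-Market triplet (+ side files)."""
    path = Path(path)
    if format == "tsv":
        matrix.to_frame().to_csv(path, sep="\t")
        return
    if format == "matrix_market_triplet":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(matrix.values))
        with open(path.parent / "genes.tsv", "w") as fh:
            fh.write("\n".join(matrix.gene_ids) + "\n")
        with open(path.parent / "cells.tsv", "w") as fh:
            fh.write("\n".join(matrix.cell_ids) + "\n")
        return
    raise ValueError(f"unknown matrix format {format!r}")


# ---------------------------------------------------------------------------
# generic result tables


def write_table(records, path: str | Path) -> None:
    """Write a result table (DataFrame or a sequence of dataclasses) as TSV.

    An empty sequence of dataclasses still produces a header-only file when
    the element type is known (pass a DataFrame for full control).
    """
    if records is None:
        raise ValueError("records must not be None")
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"directory {path.parent} does not exist")
    if isinstance(records, pd.DataFrame):
        records.to_csv(path, sep="\t", index=False)
        return
    records = list(records)
    if records and dataclasses.is_dataclass(records[0]):
        df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    else:
        df = pd.DataFrame(records)
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
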