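"""Signature-matrix and annotation I/O.

Signatures travel as GCT text files (the CMap/LINCS convention): a version
line ``#1.2``, a dimension line ``<genes>\\t<samples>``, a header row
``NAME\\tDescription\\t<sample ids...>`` and one row per gene.  The ``#1.3``
dialect (extra row/column metadata blocks) is read by skipping the metadata;
only the expression block is consumed.  Sample annotations are plain TSV.

Gene matching everywhere in this package is by exact string identity of
gene ids; probe-to-symbol mapping is an upstream responsibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CoverageError,
    FormatError,
    ParseError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureMatrix",
    "SampleAnnotation",
    "read_gct",
    "write_gct",
    "read_annotations",
    "write_annotations",
    "align_genes",
]


@dataclass
class SignatureMatrix:
    """Genes x samples matrix of differential-expression scores.

    Rows are genes, columns are samples; values are unitless
    differential-expression statistics (e.g., moderated z-scores).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        dup = _duplicates(self.gene_ids)
        if dup:
            raise ValidationError(f"duplicate gene ids: {sorted(dup)}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ValidationError(f"duplicate sample ids: {sorted(dup)}")
        if self.values.ndim != 2 or self.values.shape != (
            len(self.gene_ids),
            len(self.sample_ids),
        ):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def select_samples(self, sample_ids: list[str]) -> "SignatureMatrix":
        """Restrict to the given samples, in the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        idx = [pos[s] for s in sample_ids]
        return SignatureMatrix(list(self.gene_ids), list(sample_ids), self.values[:, idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignatureMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and self.values.shape == other.values.shape
            and bool(np.all(self.values == other.values))
        )


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample metadata keyed to a signature-matrix column.

    ``dosage`` is informational only: replicates of a compound at different
    dosages share one class label throughout the pipeline.
    """

    sample_id: str
    compound: str
    cell_line: str
    time_point: int
    dosage: str = ""

    def __post_init__(self) -> None:
        if self.time_point <= 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: time_point must be > 0, got {self.time_point}"
            )


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def read_gct(path) -> SignatureMatrix:
    """Read a GCT ``#1.2`` or ``#1.3`` file into a :class:`SignatureMatrix`.

    For ``#1.3`` files the row/column metadata blocks are skipped; only the
    expression values are returned.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file (line 1: missing version line)")
    version = lines[0].strip()
    if version not in ("#1.2", "#1.3"):
        raise FormatError(f"{path}: line 1: expected '#1.2' or '#1.3', got {version!r}")
    if len(lines) < 3:
        raise FormatError(f"{path}: line 2: missing dimension or header line")
    dims = lines[1].split("\t")
    if version == "#1.2":
        if len(dims) < 2:
            raise FormatError(f"{path}: line 2: expected '<rows>\\t<cols>'")
        n_row_meta, n_col_meta = 0, 0
    else:
        if len(dims) < 4:
            raise FormatError(
                f"{path}: line 2: #1.3 expects '<rows>\\t<cols>\\t<rowmeta>\\t<colmeta>'"
            )
        try:
            n_row_meta, n_col_meta = int(dims[2]), int(dims[3])
        except ValueError as exc:
            raise FormatError(f"{path}: line 2: non-integer metadata counts") from exc
    try:
        n_rows, n_cols = int(dims[0]), int(dims[1])
    except ValueError as exc:
        raise FormatError(f"{path}: line 2: non-integer dimensions") from exc
    if n_rows < 1 or n_cols < 1:
        raise FormatError(f"{path}: line 2: dimensions must be >= 1")

    header = lines[2].split("\t")
    # #1.2 header: NAME, Description, samples...  #1.3: id, <rowmeta names...>, samples...
    n_lead = 2 if version == "#1.2" else 1 + n_row_meta
    sample_ids = header[n_lead:]
    if len(sample_ids) != n_cols:
        raise FormatError(
            f"{path}: line 3: header names {len(sample_ids)} samples, "
            f"dimension line declares {n_cols}"
        )
    body = lines[3 + n_col_meta :]
    body = [ln for ln in body if ln != ""]
    if len(body) != n_rows:
        raise FormatError(
            f"{path}: body has {len(body)} data rows, header declares {n_rows}"
        )
    gene_ids: list[str] = []
    values = np.empty((n_rows, n_cols), dtype=np.float64)
    for i, line in enumerate(body):
        fields = line.split("\t")
        if len(fields) != n_lead + n_cols:
            raise FormatError(
                f"{path}: line {4 + n_col_meta + i}: expected {n_lead + n_cols} "
                f"fields, got {len(fields)}"
            )
        gene_ids.append(fields[0])
        for j, cell in enumerate(fields[n_lead:]):
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at gene row {i + 1} "
                    f"({fields[0]!r}), sample column {j + 1} ({sample_ids[j]!r})"
                ) from exc
    dup = _duplicates(gene_ids)
    if dup:
        raise ValidationError(f"{path}: duplicate gene ids: {sorted(dup)}")
    return SignatureMatrix(gene_ids, sample_ids, values)


def write_gct(matrix: SignatureMatrix, path) -> None:
    """Write the ``#1.2`` GCT dialect with repr-round-trip-safe floats."""
    if matrix.n_samples < 1:
        raise FormatError("GCT requires at least one sample column")
    if matrix.n_genes < 1:
        raise FormatError("GCT requires at least one gene row")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
        fh.write("NAME\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, gene in enumerate(matrix.gene_ids):
            row = "\t".join(repr(v) for v in matrix.values[i].tolist())
            fh.write(f"{gene}\t{gene}\t{row}\n")


_REQUIRED_ANNOTATION_COLUMNS = ("sample_id", "compound", "cell_line", "time_point", "dosage")


def read_annotations(path) -> list[SampleAnnotation]:
    """Read a sample-annotation TSV; extra columns are ignored."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in _REQUIRED_ANNOTATION_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    dup = _duplicates(list(table["sample_id"]))
    if dup:
        raise ValidationError(f"{path}: duplicate sample ids: {sorted(dup)}")
    out = []
    for _, row in table.iterrows():
        try:
            tp = int(row["time_point"])
        except ValueError as exc:
            raise ParseError(
                f"{path}: sample {row['sample_id']!r}: non-integer time_point "
                f"{row['time_point']!r}"
            ) from exc
        out.append(
            SampleAnnotation(
                sample_id=str(row["sample_id"]),
                compound=str(row["compound"]),
                cell_line=str(row["cell_line"]),
                time_point=tp,
                dosage="" if pd.isna(row["dosage"]) else str(row["dosage"]),
            )
        )
    return out


def write_annotations(annotations: list[SampleAnnotation], path) -> None:
    table = pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in annotations],
            "compound": [a.compound for a in annotations],
            "cell_line": [a.cell_line for a in annotations],
            "time_point": [a.time_point for a in annotations],
            "dosage": [a.dosage for a in annotations],
        }
    )
    table.to_csv(path, sep="\t", index=False)


def align_genes(
    query: SignatureMatrix,
    model_gene_ids: list[str],
    min_overlap_fraction: float = 0.8,
) -> tuple[SignatureMatrix, float]:
    """Restrict and reorder a query to a model's gene space.

    Genes in the model but absent from the query are filled with 0, the
    neutral value of a differential-expression score; query genes absent
    from the model are dropped.  Returns the aligned matrix and the overlap
    fraction |shared| / |model genes|.

    Raises :class:`CoverageError` when the overlap fraction is below
    ``min_overlap_fraction``.
    """
    if not 0 < min_overlap_fraction <= 1:
        raise ValidationError(
            f"min_overlap_fraction must be in (0, 1], got {min_overlap_fraction}"
        )
    model_gene_ids = [str(g) for g in model_gene_ids]
    query_pos = {g: i for i, g in enumerate(query.gene_ids)}
    shared = [g for g in model_gene_ids if g in query_pos]
    overlap = len(shared) / len(model_gene_ids)
    if overlap < min_overlap_fraction:
        raise CoverageError(
            f"query covers only {overlap:.3f} of the model's genes "
            f"(required {min_overlap_fraction})"
        )
    extras = len(query.gene_ids) - len(shared)
    if extras:
        logger.info("align_genes: dropped %d query genes absent from the model", extras)
    values = np.zeros((len(model_gene_ids), query.n_samples))
    for i, g in enumerate(model_gene_ids):
        j = query_pos.get(g)
        if j is not None:
            values[i] = query.values[j]
    return SignatureMatrix(model_gene_ids, list(query.sample_ids), values), overlap
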