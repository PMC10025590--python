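"""Quality control and condition-wise splitting of signature collections.

Transcriptional responses to a compound depend strongly on the cell line
and the treatment duration, while dosage has only a weak effect.  The
pipeline therefore (1) keeps only signatures measured in a whitelist of
cell lines at a whitelist of time points, and (2) splits the surviving
collection into one training subset per (cell line, time point) pair.
Within a subset, samples treated with the same compound at different
dosages are replicates of one class.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import NamedTuple

from .errors import EmptySelectionError, SubsetLookupError, ValidationError
from .io import (
    SampleAnnotation,
    SignatureMatrix,
    read_annotations,
    read_gct,
    write_annotations,
    write_gct,
)

logger = logging.getLogger(__name__)

#: The LINCS cell lines used for training by default: nine cancer lines
#: plus the two non-cancer lines HA1E and NPC.
DEFAULT_CELL_LINES = frozenset(
    {"MCF7", "A375", "PC3", "HT29", "A549", "BT20", "VCAP", "HCC515", "HEPG2", "HA1E", "NPC"}
)
#: Treatment durations, in hours, retained by default.
DEFAULT_TIME_POINTS = frozenset({6, 24})


class SubsetKey(NamedTuple):
    cell_line: str
    time_point: int


SubsetCollection = dict[SubsetKey, tuple[SignatureMatrix, list[SampleAnnotation]]]


def _check_cover(matrix: SignatureMatrix, annotations: list[SampleAnnotation]) -> dict:
    by_id = {a.sample_id: a for a in annotations}
    missing = [s for s in matrix.sample_ids if s not in by_id]
    if missing:
        raise ValidationError(f"annotations missing for samples: {missing[:5]}")
    return by_id


def qc_filter(
    matrix: SignatureMatrix,
    annotations: list[SampleAnnotation],
    allowed_cell_lines=DEFAULT_CELL_LINES,
    allowed_time_points=DEFAULT_TIME_POINTS,
) -> tuple[SignatureMatrix, list[SampleAnnotation]]:
    """Keep samples whose cell line and time point are whitelisted."""
    by_id = _check_cover(matrix, annotations)
    allowed_cell_lines = set(allowed_cell_lines)
    allowed_time_points = set(allowed_time_points)
    keep = [
        s
        for s in matrix.sample_ids
        if by_id[s].cell_line in allowed_cell_lines
        and by_id[s].time_point in allowed_time_points
    ]
    removed = matrix.n_samples - len(keep)
    if not keep:
        raise EmptySelectionError(
            f"no samples pass QC (cell lines {sorted(allowed_cell_lines)}, "
            f"time points {sorted(allowed_time_points)})"
        )
    if removed:
        logger.info("qc_filter: removed %d of %d samples", removed, matrix.n_samples)
    return matrix.select_samples(keep), [by_id[s] for s in keep]


def split_by_condition(
    matrix: SignatureMatrix, annotations: list[SampleAnnotation]
) -> SubsetCollection:
    """Partition samples into one subset per observed (cell line, time point)."""
    by_id = _check_cover(matrix, annotations)
    groups: dict[SubsetKey, list[str]] = {}
    for s in matrix.sample_ids:
        a = by_id[s]
        groups.setdefault(SubsetKey(a.cell_line, a.time_point), []).append(s)
    return {
        key: (matrix.select_samples(ids), [by_id[s] for s in ids])
        for key, ids in groups.items()
    }


def select_reference_subset(
    collection: SubsetCollection, query_cell_line: str, query_time_point: int
) -> tuple[SignatureMatrix, list[SampleAnnotation]]:
    """Return the subset matching the query's cell line and time point."""
    key = SubsetKey(query_cell_line, int(query_time_point))
    if key not in collection:
        available = sorted((k.cell_line, k.time_point) for k in collection)
        raise SubsetLookupError(
            f"no reference subset for {key}; available: {available}"
        )
    return collection[key]


def filter_min_replicates(
    matrix: SignatureMatrix,
    annotations: list[SampleAnnotation],
    min_replicates: int = 2,
) -> tuple[SignatureMatrix, list[SampleAnnotation]]:
    """Drop compound classes with fewer than ``min_replicates`` samples.

    The default of 2 is the minimum for LDA's within-class scatter to be
    defined for every class.
    """
    if min_replicates < 1:
        raise ValidationError(f"min_replicates must be >= 1, got {min_replicates}")
    by_id = _check_cover(matrix, annotations)
    counts = Counter(a.compound for a in annotations)
    dropped = sorted(c for c, n in counts.items() if n < min_replicates)
    if dropped:
        logger.info("filter_min_replicates: dropped classes %s", dropped)
    keep = [s for s in matrix.sample_ids if counts[by_id[s].compound] >= min_replicates]
    if not keep:
        raise EmptySelectionError(
            f"every compound class has fewer than {min_replicates} replicates"
        )
    return matrix.select_samples(keep), [by_id[s] for s in keep]


def save_subsets(collection: SubsetCollection, out_dir) -> None:
    """Persist each subset as ``<cell_line>_<time_point>h/`` with GCT + TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, (matrix, annotations) in collection.items():
        sub = out / f"{key.cell_line}_{key.time_point}h"
        sub.mkdir(exist_ok=True)
        write_gct(matrix, sub / "signatures.gct")
        write_annotations(annotations, sub / "annotations.tsv")


def load_subsets(in_dir) -> SubsetCollection:
    """Load a directory written by :func:`save_subsets`."""
    collection: SubsetCollection = {}
    for sub in sorted(Path(in_dir).iterdir()):
        if not sub.is_dir() or "_" not in sub.name or not sub.name.endswith("h"):
            continue
        cell_line, tp = sub.name.rsplit("_", 1)
        key = SubsetKey(cell_line, int(tp[:-1]))
        collection[key] = (
            read_gct(sub / "signatures.gct"),
            read_annotations(sub / "annotations.tsv"),
        )
    return collection
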