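"""Readers and writers for the TSV/CSV inputs.

All readers share the same conventions: UTF-8 text with a header row;
the first column holds row ids, which are kept as opaque strings in file
order. Missing-value tokens accepted on read are the empty string, "NA"
and "NaN" (case-insensitive).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .datamodel import (
    AlterationRecord,
    AlterationTable,
    AnnotationTable,
    LabeledMatrix,
    SceneMapError,
    is_missing_token,
)

logger = logging.getLogger(__name__)

# MAF column-name defaults for alteration tables
DEFAULT_SAMPLE_COL = "Tumor_Sample_Barcode"
DEFAULT_GENE_COL = "Hugo_Symbol"
DEFAULT_CATEGORY_COL = "Variant_Classification"


def _read_table(path, delimiter: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SceneMapError(f"no such file: {path}")
    try:
        frame = pd.read_csv(
            path,
            sep=delimiter,
            dtype=str,
            index_col=0,
            keep_default_na=False,
            engine="python",
        )
    except pd.errors.EmptyDataError as exc:
        raise SceneMapError(f"empty table: {path}") from exc
    except pd.errors.ParserError as exc:  # ragged rows: pandas names the line
        raise SceneMapError(f"malformed table {path}: {exc}") from exc
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise SceneMapError(f"empty table: {path}")
    _check_axis_unique(frame.index, "row", path)
    _check_axis_unique(frame.columns, "column", path)
    return frame


def _check_axis_unique(axis, what: str, path) -> None:
    seen: set[str] = set()
    for i in axis:
        s = str(i)
        if s in seen:
            raise SceneMapError(f"duplicate {what} id {s!r} in {path}")
        seen.add(s)


def read_matrix(path, delimiter: str = "\t") -> LabeledMatrix:
    """Read a numeric matrix: header = column ids, first field = row id.

    Cells that do not parse as numbers (including the missing tokens)
    become missing values.
    """
    frame = _read_table(path, delimiter)

    def parse(cell: str) -> float:
        # exact float() parsing: correctly rounded, unlike pandas' fast path
        try:
            return float(cell)
        except ValueError:
            return float("nan")

    values = [[parse(c) for c in row] for row in frame.to_numpy(dtype=str)]
    return LabeledMatrix(
        values=values,
        row_ids=[str(i) for i in frame.index],
        col_ids=[str(c) for c in frame.columns],
    )


def write_matrix(matrix: LabeledMatrix, path, delimiter: str = "\t") -> None:
    """Write a matrix in the format :func:`read_matrix` accepts.

    Missing values are written as "NA". Floats use repr precision so a
    read-back round-trip reproduces values within float text precision.
    """
    frame = matrix.to_frame()
    frame.index.name = "id"
    frame.to_csv(path, sep=delimiter, na_rep="NA", float_format="%.17g")


def read_annotation(path, delimiter: str = "\t") -> AnnotationTable:
    """Read an annotation table, auto-tagging columns numeric/categorical."""
    frame = _read_table(path, delimiter)
    return AnnotationTable.from_frame(frame)


def read_alterations(
    path,
    sample_col: str = DEFAULT_SAMPLE_COL,
    gene_col: str = DEFAULT_GENE_COL,
    category_col: str = DEFAULT_CATEGORY_COL,
    delimiter: str = "\t",
) -> AlterationTable:
    """Read a MAF-like long table into an :class:`AlterationTable`.

    Rows whose category cell is missing are dropped; the number dropped is
    recorded on the returned table and logged.
    """
    path = Path(path)
    if not path.exists():
        raise SceneMapError(f"no such file: {path}")
    frame = pd.read_csv(
        path, sep=delimiter, dtype=str, keep_default_na=False, engine="python"
    )
    for col in (sample_col, gene_col, category_col):
        if col not in frame.columns:
            raise SceneMapError(
                f"column {col!r} not found in {path} "
                f"(has: {', '.join(map(str, frame.columns))})"
            )
    records: list[AlterationRecord] = []
    n_dropped = 0
    for _, row in frame.iterrows():
        cat = str(row[category_col])
        if is_missing_token(cat):
            n_dropped += 1
            continue
        records.append(
            AlterationRecord(
                sample_id=str(row[sample_col]).strip(),
                gene_id=str(row[gene_col]).strip(),
                category=cat.strip(),
            )
        )
    if n_dropped:
        logger.info("read_alterations: dropped %d rows with empty category", n_dropped)
    return AlterationTable(records=records, n_dropped=n_dropped)
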