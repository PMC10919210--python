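"""Core in-memory containers for heatmap inputs.

The engine consumes four kinds of tabular input: a labeled numeric matrix
(the heatmap body), per-row/per-column annotation tables with mixed
categorical and numeric columns, long-form alteration records (sample,
gene, category — the oncoPrint input), and long-form dot records (row,
column, value, color value, optional hue — the dot-heatmap input).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd


class SceneMapError(ValueError):
    """Raised for invalid inputs anywhere in the engine."""


#: Cell tokens treated as missing on read (compared case-insensitively,
#: after stripping whitespace).
MISSING_TOKENS = frozenset({"", "na", "nan"})


def is_missing_token(cell: str) -> bool:
    return cell.strip().lower() in MISSING_TOKENS


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise SceneMapError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class LabeledMatrix:
    """A 2-D grid of real numbers with ordered, unique row and column ids.

    Missing cells are NaN. This is the heatmap body; row/column order is
    meaningful (file order on read, display order after clustering).
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_ids = [str(c) for c in self.col_ids]
        if self.values.ndim != 2:
            raise SceneMapError("matrix values must be 2-dimensional")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise SceneMapError(
                f"shape {self.values.shape} does not match "
                f"{len(self.row_ids)} row ids x {len(self.col_ids)} column ids"
            )
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise SceneMapError("matrix needs at least one row and one column")
        _check_unique(self.row_ids, "row")
        _check_unique(self.col_ids, "column")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LabeledMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            row_ids=[str(i) for i in frame.index],
            col_ids=[str(c) for c in frame.columns],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.row_ids), columns=list(self.col_ids)
        )

    def take_rows(self, indices: Sequence[int]) -> "LabeledMatrix":
        idx = list(indices)
        return LabeledMatrix(
            self.values[idx, :], [self.row_ids[i] for i in idx], list(self.col_ids)
        )

    def take_cols(self, indices: Sequence[int]) -> "LabeledMatrix":
        idx = list(indices)
        return LabeledMatrix(
            self.values[:, idx], list(self.row_ids), [self.col_ids[i] for i in idx]
        )


@dataclass
class AnnotationColumn:
    """One named annotation vector, tagged categorical or numeric.

    ``kind`` drives downstream track defaults: categorical columns render
    as discrete color bars with a patch legend, numeric ones as continuous
    color bars / bar annotations. For categorical columns, ``levels`` holds
    the distinct values in first-appearance order (legend and split order).
    """

    name: str
    kind: str  # "categorical" | "numeric"
    values: list[Any]

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "numeric"):
            raise SceneMapError(f"unknown annotation column kind: {self.kind!r}")

    @property
    def levels(self) -> list[str]:
        if self.kind != "categorical":
            raise SceneMapError(f"column {self.name!r} is not categorical")
        out: list[str] = []
        for v in self.values:
            if v is not None and v not in out:
                out.append(v)
        return out


@dataclass
class AnnotationTable:
    """Per-row or per-column metadata: an ordered index plus tagged columns."""

    index_ids: list[str]
    columns: dict[str, AnnotationColumn] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.index_ids = [str(i) for i in self.index_ids]
        _check_unique(self.index_ids, "index")
        for name, col in self.columns.items():
            if len(col.values) != len(self.index_ids):
                raise SceneMapError(
                    f"annotation column {name!r} has {len(col.values)} entries "
                    f"for {len(self.index_ids)} index ids"
                )

    def __getitem__(self, name: str) -> AnnotationColumn:
        try:
            return self.columns[name]
        except KeyError:
            raise SceneMapError(f"no annotation column named {name!r}") from None

    def mapping(self, name: str) -> dict[str, Any]:
        """Column values keyed by index id."""
        col = self[name]
        return dict(zip(self.index_ids, col.values))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AnnotationTable":
        """Build from a DataFrame of raw strings, auto-tagging each column.

        A column is numeric when every non-missing cell parses as a real
        number; otherwise it is categorical (missing cells become None).
        """
        index_ids = [str(i) for i in frame.index]
        columns: dict[str, AnnotationColumn] = {}
        for name in frame.columns:
            raw = [str(v) for v in frame[name]]
            columns[str(name)] = _autotag_column(str(name), raw)
        return cls(index_ids=index_ids, columns=columns)


def _autotag_column(name: str, raw: list[str]) -> AnnotationColumn:
    observed = [c for c in raw if not is_missing_token(c)]
    parsed = pd.to_numeric(pd.Series(observed, dtype=object), errors="coerce")
    if len(observed) > 0 and not parsed.isna().any():
        vals = [
            float(c) if not is_missing_token(c) else math.nan for c in (s.strip() for s in raw)
        ]
        return AnnotationColumn(name, "numeric", vals)
    vals_cat = [None if is_missing_token(c) else c.strip() for c in raw]
    return AnnotationColumn(name, "categorical", vals_cat)


@dataclass(frozen=True)
class AlterationRecord:
    sample_id: str
    gene_id: str
    category: str


@dataclass
class AlterationTable:
    """Long-form (sample, gene, category) records — MAF-like oncoPrint input.

    A (sample, gene) pair may repeat with different categories: co-occurring
    alterations in one cell.
    """

    records: list[AlterationRecord]
    n_dropped: int = 0  # rows discarded on read for an empty category

    def __post_init__(self) -> None:
        for r in self.records:
            if not r.sample_id or not r.gene_id or not r.category:
                raise SceneMapError(f"alteration record with empty field: {r}")

    @property
    def samples(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.sample_id not in out:
                out.append(r.sample_id)
        return out

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.gene_id not in out:
                out.append(r.gene_id)
        return out

    @property
    def categories(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.category not in out:
                out.append(r.category)
        return out


@dataclass(frozen=True)
class DotRecord:
    row_key: str
    col_key: str
    value: float
    color_value: Any = None  # real or category; defaults to value downstream
    hue: str | None = None


@dataclass
class DotTable:
    """Long-form dot-heatmap records: one dot per (row, column) cell.

    ``value`` drives dot size, ``color_value`` the fill (numeric or
    categorical), ``hue`` the marker shape. At most one record per
    (row, col, hue) triple; values must be finite.
    """

    records: list[DotRecord]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str | None]] = set()
        for r in self.records:
            if not math.isfinite(r.value):
                raise SceneMapError(
                    f"non-finite dot value at ({r.row_key!r}, {r.col_key!r})"
                )
            key = (r.row_key, r.col_key, r.hue)
            if key in seen:
                raise SceneMapError(f"duplicate dot record for {key}")
            seen.add(key)

    @property
    def row_keys(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.row_key not in out:
                out.append(r.row_key)
        return out

    @property
    def col_keys(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.col_key not in out:
                out.append(r.col_key)
        return out
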