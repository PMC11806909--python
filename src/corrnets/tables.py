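"""Feature-table containers, CSV input/output and preprocessing transforms.

A *feature table* is the universal input of the pipeline: a samples x
features numeric matrix, e.g. bacterial taxon counts per fecal sample or
clr-transformed abundances.  Any numeric feature table is valid; feature
labels are opaque strings (taxonomy strings, gene ids, metabolite names).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "NameMap",
    "read_feature_table",
    "map_columns",
    "clr_transform",
    "write_table",
]


@dataclass(frozen=True)
class FeatureTable:
    """Samples x features numeric matrix with row and column labels.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique row labels (one per sample).
    feature_ids : sequence of str
        Unique column labels (one per feature).
    values : ndarray of shape (n_samples, n_features)
        Dense float matrix; no missing entries.
    """

    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        object.__setattr__(self, "values", values)
        n, p = values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_ids) != p:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {p} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if len(set(self.feature_ids)) != p:
            raise ValueError("feature_ids must be unique")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(),
            index=list(self.sample_ids),
            columns=list(self.feature_ids),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureTable":
        return cls(
            sample_ids=tuple(str(i) for i in frame.index),
            feature_ids=tuple(str(c) for c in frame.columns),
            values=frame.to_numpy(dtype=float),
        )

    def write_csv(self, path: str | Path) -> None:
        """Write the table as CSV with sample ids in the first column."""
        self.to_frame().to_csv(path, index=True, index_label="sample_id")


@dataclass(frozen=True)
class NameMap:
    """Bijection between original feature labels and standardized X1..Xp labels.

    Long taxonomy strings make network figures unreadable; the pipeline
    relabels features to "X1", "X2", ... in original column order and keeps
    this map so the original names can always be recovered.
    """

    to_original: Mapping[str, str]  # "X1" -> original label

    @property
    def to_standard(self) -> dict[str, str]:
        return {orig: std for std, orig in self.to_original.items()}

    def original(self, standard_label: str) -> str:
        return self.to_original[standard_label]

    def standard(self, original_label: str) -> str:
        return self.to_standard[original_label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "standardized": list(self.to_original.keys()),
                "original": list(self.to_original.values()),
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_feature_table(
    path: str | Path,
    drop_columns: Sequence[str] = (),
    transpose: bool = False,
) -> FeatureTable:
    """Read a CSV feature table, dropping listed metadata columns.

    The first CSV column holds sample identifiers; remaining columns are
    features.  Metadata removal is explicit via ``drop_columns`` — nothing is
    inferred.  Any retained cell that does not parse as a number (including
    "NA" and empty cells) raises a ``ValueError`` naming the offending cell.

    Parameters
    ----------
    path : path
        CSV file with a header row; first column = sample ids.
    drop_columns : sequence of str
        Column names to remove (metadata such as treatment group or time).
    transpose : bool
        Set when the file is features-by-samples; the matrix is transposed
        after reading so the result is always samples x features.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")

    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh))
    feature_names = header[1:]
    dupes = {name for name in feature_names if feature_names.count(name) > 1}
    if dupes:
        raise ValueError(f"duplicate feature names in {path.name}: {sorted(dupes)}")

    # keep_default_na=False so "NA" cells surface as parse errors, not NaN
    frame = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    frame.columns = [str(c) for c in frame.columns]

    missing = [c for c in drop_columns if c not in frame.columns]
    if missing:
        raise ValueError(f"drop_columns not present in table: {missing}")
    frame = frame.drop(columns=list(drop_columns))
    if frame.shape[1] == 0:
        raise ValueError("no feature columns remain after dropping metadata")

    numeric = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=float)
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = frame.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric value {frame.loc[row, col]!r} at row {row!r}, "
                f"column {col!r}"
            )
        numeric[col] = converted

    if transpose:
        numeric = numeric.T
    return FeatureTable.from_frame(numeric)


def map_columns(table: FeatureTable) -> tuple[FeatureTable, NameMap]:
    """Relabel features to "X1".."Xp" in original column order.

    Returns the relabeled table and a :class:`NameMap` whose inverse recovers
    the original labels exactly.
    """
    if table.n_features < 1:
        raise ValueError("table has no features")
    standardized = tuple(f"X{i + 1}" for i in range(table.n_features))
    name_map = NameMap(dict(zip(standardized, table.feature_ids)))
    relabeled = FeatureTable(table.sample_ids, standardized, table.values)
    return relabeled, name_map


def clr_transform(table: FeatureTable, pseudocount: float = 1.0) -> FeatureTable:
    """Centered log-ratio transform, row-wise, with a pseudocount.

    Each sample row ``x`` is mapped to ``log(x_j + c) - mean_j log(x_j + c)``,
    taking compositional count data to an unconstrained scale where ordinary
    correlations are meaningful.  Output rows sum to zero.

    Parameters
    ----------
    table : FeatureTable
        Nonnegative values (counts or relative abundances).
    pseudocount : float
        Positive offset ``c`` added before taking logs, so zero counts are
        representable.  Default 1.0 for count tables.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    if np.any(table.values < 0):
        i, j = np.argwhere(table.values < 0)[0]
        raise ValueError(
            f"negative value at sample {table.sample_ids[i]!r}, "
            f"feature {table.feature_ids[j]!r}; clr requires nonnegative input"
        )
    logged = np.log(table.values + pseudocount)
    centered = logged - logged.mean(axis=1, keepdims=True)
    return FeatureTable(table.sample_ids, table.feature_ids, centered)


def write_table(
    rows: Iterable[Mapping[str, object]] | pd.DataFrame,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write a result table as UTF-8 CSV with a header row.

    ``rows`` is either a DataFrame or an iterable of dicts sharing identical
    keys.  ``columns`` names the header explicitly; required to get a
    header-only file from an empty row list.
    """
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        rows = list(rows)
        if rows:
            keys = list(rows[0].keys())
            for r in rows[1:]:
                if list(r.keys()) != keys:
                    raise ValueError("all rows must have identical keys in the same order")
        else:
            keys = list(columns or [])
        frame = pd.DataFrame(rows, columns=columns if columns is not None else keys)
    frame.to_csv(path, index=False, encoding="utf-8", float_format=_float_fmt)


def _float_fmt(x: float) -> str:
    # repr of a builtin float round-trips IEEE doubles exactly (numpy scalar
    # reprs do not parse back, so coerce first)
    if math.isfinite(x):
        return repr(float(x))
    return str(float(x))
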