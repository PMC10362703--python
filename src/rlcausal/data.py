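"""Observation tables: reading, validation and per-column normalization.

The pipeline consumes an m x d matrix of continuous measurements (rows are
subjects, columns are risk factors).  All downstream stages -- BIC scoring,
the policy network and the spacing entropy estimator -- assume finite values
and non-constant columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Dataset", "read_table", "normalize"]


class TableFormatError(ValueError):
    """Raised when an input table cannot be parsed into a numeric matrix."""


@dataclass(frozen=True)
class Dataset:
    """An m x d matrix of finite real observations with named columns."""

    values: np.ndarray
    columns: tuple = field(default=None)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if values.shape[0] < 2 or values.shape[1] < 2:
            raise TableFormatError(
                f"need at least 2 rows and 2 columns, got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise TableFormatError(f"non-finite entry at row {r}, column {c}")
        columns = self.columns
        if columns is None:
            columns = tuple(f"X{j + 1}" for j in range(values.shape[1]))
        else:
            columns = tuple(str(c) for c in columns)
        if len(columns) != values.shape[1]:
            raise ValueError("number of column names must match number of columns")
        if len(set(columns)) != len(columns):
            raise ValueError("column names must be unique")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "columns", columns)

    @property
    def m(self) -> int:
        """Number of observations (rows)."""
        return self.values.shape[0]

    @property
    def d(self) -> int:
        """Number of variables (columns)."""
        return self.values.shape[1]

    def column(self, name_or_index) -> np.ndarray:
        if isinstance(name_or_index, str):
            name_or_index = self.columns.index(name_or_index)
        return self.values[:, name_or_index]


def _first_row_is_header(first_fields) -> bool:
    # Header iff any cell in the first row fails numeric parsing.
    for cell in first_fields:
        try:
            float(cell)
        except (TypeError, ValueError):
            return True
    return False


def read_table(path, delimiter: str = ",") -> Dataset:
    """Read a delimited numeric table into a :class:`Dataset`.

    The first row is treated as a header when any of its cells is
    non-numeric; otherwise columns are named ``X1 .. Xd``.

    Raises
    ------
    TableFormatError
        If any data cell is non-numeric (the error names the offending
        row and column) or the table has fewer than 2 rows or columns.
    """
    raw = pd.read_csv(path, sep=delimiter, header=None, dtype=str,
                      skip_blank_lines=True)
    if raw.empty:
        raise TableFormatError(f"{path}: table is empty")
    first = raw.iloc[0].tolist()
    if _first_row_is_header(first):
        columns = [str(c).strip() for c in first]
        body = raw.iloc[1:]
    else:
        columns = None
        body = raw
    if body.shape[0] < 2 or body.shape[1] < 2:
        raise TableFormatError(
            f"{path}: need at least 2 data rows and 2 columns, "
            f"got {body.shape[0]} rows x {body.shape[1]} columns"
        )
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & body.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        col_name = columns[c] if columns else f"X{c + 1}"
        raise TableFormatError(
            f"{path}: non-numeric cell {body.iat[r, c]!r} at data row "
            f"{r + 1}, column {col_name!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        col_name = columns[c] if columns else f"X{c + 1}"
        raise TableFormatError(
            f"{path}: missing value at data row {r + 1}, column {col_name!r}"
        )
    return Dataset(numeric.to_numpy(dtype=float), columns)


def normalize(data: Dataset, method: str = "minmax") -> Dataset:
    """Rescale each column independently.

    ``minmax`` (the default) maps each column's minimum to 0 and maximum
    to 1, which makes the spacing-estimator entropies comparable across
    variables of different physical units.  ``zscore`` centres to mean 0,
    standard deviation 1.

    Raises
    ------
    ValueError
        If a column is constant (both rescalings and the entropy
        estimator are undefined there); the error names the column.
    """
    values = data.values
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    span = hi - lo
    constant = np.flatnonzero(span == 0)
    if constant.size:
        names = ", ".join(repr(data.columns[j]) for j in constant)
        raise ValueError(f"constant column(s): {names}")
    if method == "minmax":
        out = (values - lo) / span
    elif method == "zscore":
        out = (values - values.mean(axis=0)) / values.std(axis=0, ddof=0)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return Dataset(out, data.columns)
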