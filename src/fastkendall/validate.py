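"""Input validation, cleaning, and pairwise correlation matrices.

``check_data`` mirrors the usual entry-point hygiene for rank
correlation: dimensions must agree, rows with a missing value in either
variable are dropped (pairwise-complete deletion), at least two
complete observations must remain, and neither variable may be
constant. NaN is the only in-memory missing marker; infinities are
legitimate ordered reals for a rank-based method. Ties are exact
floating-point equality.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import PairedSample, knight_tau
from .errors import (
    DimensionError,
    InsufficientDataError,
    ZeroVarianceError,
)

__all__ = ["check_data", "tau_matrix", "read_paired", "read_matrix"]


def _as_numeric_vector(v, name: str) -> np.ndarray:
    try:
        arr = np.asarray(v, dtype=float)
    except (TypeError, ValueError) as exc:
        raise TypeError(f"{name} must be numeric: {exc}") from None
    return arr


def check_data(x, y=None) -> PairedSample:
    """Validate and clean paired input, returning a :class:`PairedSample`.

    ``x`` may be a vector (with ``y`` its partner) or a two-column
    matrix/DataFrame with ``y`` omitted. Rows where either value is NaN
    are dropped. Idempotent: validating an already-clean sample returns
    an equal sample.

    Raises :class:`DimensionError`, :class:`InsufficientDataError`,
    :class:`ZeroVarianceError`, or :class:`TypeError` as appropriate.
    """
    if y is None:
        if isinstance(x, PairedSample):
            x, y = x.x, x.y
        else:
            mat = _as_numeric_vector(x, "x")
            if mat.ndim != 2 or mat.shape[1] != 2:
                raise DimensionError(
                    "without y, x must be a two-column matrix of paired values"
                )
            x, y = mat[:, 0], mat[:, 1]
    xv = _as_numeric_vector(x, "x")
    yv = _as_numeric_vector(y, "y")
    if xv.ndim != 1 or yv.ndim != 1:
        raise DimensionError("x and y must be one-dimensional vectors")
    if xv.shape[0] != yv.shape[0]:
        raise DimensionError(
            f"x and y must have the same length (got {xv.shape[0]} and {yv.shape[0]})"
        )
    keep = ~(np.isnan(xv) | np.isnan(yv))
    xv, yv = xv[keep], yv[keep]
    if xv.shape[0] < 2:
        raise InsufficientDataError(
            "fewer than two complete observations remain after removing missing values"
        )
    if np.unique(xv).size < 2:
        raise ZeroVarianceError("x has zero variance (a single distinct value)")
    if np.unique(yv).size < 2:
        raise ZeroVarianceError("y has zero variance (a single distinct value)")
    return PairedSample(xv, yv)


def tau_matrix(data) -> np.ndarray | pd.DataFrame:
    """Pairwise Kendall tau-b matrix over the columns of ``data``.

    Each entry (i, j) is computed on the pairwise-complete rows of
    columns i and j; the diagonal is 1. Column pairs failing validation
    (e.g. a constant column, or too few complete rows) yield NaN with a
    warning. Returns a DataFrame when given one, else an ndarray.
    """
    labels = None
    if isinstance(data, pd.DataFrame):
        labels = data.columns
        mat = data.to_numpy(dtype=float)
    else:
        mat = _as_numeric_vector(data, "data")
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise DimensionError("data must be a matrix with at least two columns")
    p = mat.shape[1]
    out = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            try:
                sample = check_data(mat[:, i], mat[:, j])
                out[i, j] = out[j, i] = knight_tau(sample).tau
            except (InsufficientDataError, ZeroVarianceError) as exc:
                warnings.warn(
                    f"tau undefined for column pair ({i}, {j}): {exc}",
                    stacklevel=2,
                )
                out[i, j] = out[j, i] = np.nan
    if labels is not None:
        return pd.DataFrame(out, index=labels, columns=labels)
    return out


def _read_frame(path, header: bool, delimiter: str | None) -> pd.DataFrame:
    if delimiter is None:
        delimiter = "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","
    return pd.read_csv(
        path,
        sep=delimiter,
        header=0 if header else None,
        na_values=["NA"],
        skipinitialspace=True,
    )


def read_paired(
    path,
    x_col=None,
    y_col=None,
    header: bool = True,
    delimiter: str | None = None,
) -> PairedSample:
    """Read two paired columns from a CSV/TSV file and validate them.

    Delimiter is inferred from the extension (``.tsv``/``.tab`` → tab,
    else comma) unless given. Columns may be selected by name (header
    files) or integer position; by default the first two columns are
    used. Empty fields and the literal ``NA`` are missing.
    """
    df = _read_frame(path, header, delimiter)
    if df.shape[1] < 2:
        raise DimensionError("input file must contain at least two columns")

    def pick(col, default_pos):
        if col is None:
            return df.iloc[:, default_pos]
        if isinstance(col, int) or (isinstance(col, str) and col.isdigit()):
            return df.iloc[:, int(col)]
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found (have: {list(df.columns)})")
        return df[col]

    return check_data(pick(x_col, 0), pick(y_col, 1))


def read_matrix(path, header: bool = True, delimiter: str | None = None) -> pd.DataFrame:
    """Read a numeric matrix (all columns) from a CSV/TSV file."""
    df = _read_frame(path, header, delimiter)
    if df.shape[1] < 2:
        raise DimensionError("input file must contain at least two columns")
    return df
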