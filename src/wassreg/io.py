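"""Delimited-table I/O for feature, score and weight matrices.

All matrices travel as plain CSV/TSV with a header row of column names and a
first column of row names. Parsing is strict: the delimiter is auto-detected
(comma or tab), names must be unique, and every cell must be a finite number —
missing values are rejected with the offending cell named, since silently
imputing imaging or score data would corrupt downstream fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["MatrixTable", "read_matrix", "write_matrix"]

ORIENTATIONS = ("features_by_samples", "samples_by_scores")


@dataclass(frozen=True)
class MatrixTable:
    """A named numeric matrix plus which way round it is oriented."""

    values: np.ndarray
    row_names: tuple
    col_names: tuple
    orientation: str

    def __post_init__(self):
        if self.orientation not in ORIENTATIONS:
            raise ValidationError(
                f"orientation must be one of {ORIENTATIONS}, got {self.orientation!r}")
        if len(self.row_names) != self.values.shape[0]:
            raise ValidationError("row name count does not match matrix rows")
        if len(self.col_names) != self.values.shape[1]:
            raise ValidationError("column name count does not match matrix columns")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.row_names),
                            columns=list(self.col_names))


def _detect_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if not first.strip():
        raise ValidationError(f"{path}: file is empty")
    return "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","


def read_matrix(path, orientation: str) -> MatrixTable:
    """Parse a delimited table into a :class:`MatrixTable`.

    The first row holds column names, the first column row names. Any cell
    that does not parse as a finite number (including NA markers) raises a
    :class:`ValidationError` naming the row and column.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    sep = _detect_delimiter(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split(sep)
    # pandas silently renames duplicate header names, so check them ourselves
    col_names = [str(c) for c in header[1:]]
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, header=0,
                     keep_default_na=False, encoding="utf-8")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{path}: table has no data cells")
    row_names = [str(r) for r in df.index]
    for names, kind in ((row_names, "row"), (col_names, "column")):
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise ValidationError(f"{path}: duplicate {kind} name {dup!r}")
    values = np.empty(df.shape, dtype=float)
    for j in range(df.shape[1]):
        raw = df.iloc[:, j].to_numpy(dtype=object)
        try:
            # numpy's string->float path is correctly rounded (strtod)
            col = np.asarray(raw, dtype=float)
        except ValueError:
            col = np.full(raw.shape, np.nan)
            for i, cell in enumerate(raw):
                try:
                    col[i] = float(cell)
                except ValueError:
                    raise ValidationError(
                        f"{path}: non-numeric cell at row {row_names[i]!r}, "
                        f"column {col_names[j]!r}: {cell!r}") from None
        bad = np.flatnonzero(~np.isfinite(col))
        if bad.size:
            i = int(bad[0])
            raise ValidationError(
                f"{path}: non-finite cell at row {row_names[i]!r}, "
                f"column {col_names[j]!r}: {raw[i]!r}")
        values[:, j] = col
    return MatrixTable(values=values, row_names=tuple(row_names),
                       col_names=tuple(col_names), orientation=orientation)


def write_matrix(table: MatrixTable, path, sep: str = ",") -> None:
    """Write a :class:`MatrixTable` as a delimited text file (round-trips)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_frame().to_csv(path, sep=sep, float_format="%.17g", encoding="utf-8")
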