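"""Reading and writing feature tables and targets.

Tables are CSV/TSV with a header row of unique feature names and a
mandatory leading sample-id column.  Cells must be numeric and present:
missing values are rejected rather than imputed, and non-numeric cells
are reported with their row/column coordinates.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "load_feature_table",
    "save_feature_table",
    "load_targets",
    "save_targets",
]


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def load_feature_table(path: str | Path) -> pd.DataFrame:
    """Load a samples x features table, validating names and values."""
    path = Path(path)
    sep = _sep(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep))
    if len(header) < 2:
        raise ValueError(f"{path}: expected a sample-id column plus features")
    feats = header[1:]
    dupes = sorted({f for f in feats if feats.count(f) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicated feature names {dupes[:5]}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicated sample ids")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"{path}: non-numeric or missing value at row {row!r}, column {col!r}"
            )
        values[:, j] = converted.to_numpy()
    out = pd.DataFrame(values, index=df.index, columns=df.columns)
    out.index.name = "sample_id"
    return out


def save_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    table.to_csv(path, sep=_sep(path), index_label="sample_id")


def load_targets(path: str | Path) -> pd.Series:
    """Load a (sample_id, target) two-column file."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if df.shape[1] != 1:
        raise ValueError(f"{path}: expected exactly one target column")
    s = df.iloc[:, 0]
    if s.isna().any():
        raise ValueError(f"{path}: missing target values")
    s.index = s.index.astype(str)
    s.name = "target"
    return s


def save_targets(target: pd.Series, path: str | Path) -> None:
    path = Path(path)
    target.rename("target").to_csv(path, sep=_sep(path), index_label="sample_id")
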