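"""Delimited-text I/O for expression matrices, labels and score tables.

Expression matrices are samples × features with a header row of feature
ids and a first column of sample ids; ``transpose=True`` accepts the
features × samples layout common for microarray exports.  Separator is
inferred from the extension (``.csv`` → comma, otherwise tab) and
``.gz`` compression is transparent.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["read_expression", "write_expression", "read_labels", "write_table"]


def _sep(path) -> str:
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[: -len(".gz")]
    return "," if name.endswith(".csv") else "\t"


def read_expression(path, transpose: bool = False) -> pd.DataFrame:
    """Read an expression matrix; returns samples × features."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if transpose:
        df = df.T
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=_sep(path))


def read_labels(path) -> pd.Series:
    """Read a 2-column (sample id, class) table into a Series."""
    df = pd.read_csv(path, sep=_sep(path), header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: labels file needs two columns (sample id, class)")
    first = str(df.iloc[0, 0]).lower()
    if first in {"sample", "sample_id", "id"}:  # tolerate a header row
        df = df.iloc[1:]
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="class")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep=_sep(path), index=index)
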