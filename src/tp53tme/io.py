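"""Readers and writers for the pipeline's plain-text artifacts.

All artifacts are TSV/CSV with documented headers: expression matrices
(genes x samples, first column gene symbols), score tables, clinical
tables, variant tables, cell tables and region masks.  Duplicate gene rows
in an expression file are collapsed by mean with a logged warning (the
probe-averaging convention for array data).
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .scoring import validate_expression

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class IOError_(ValueError):
    pass


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    if not sample.strip():
        raise IOError_(f"{path}: empty file")
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def read_expression(path: PathLike, delimiter: Optional[str] = None) -> pd.DataFrame:
    """Read a genes x samples expression matrix (TSV or CSV, sniffed).

    First column holds gene symbols, header row the sample ids.  Duplicate
    gene rows are averaged (logged); duplicate sample ids or non-numeric
    cells are errors.
    """
    path = Path(path)
    delim = delimiter or _sniff_delimiter(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delim)[1:]
    seen = pd.Index(header)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise IOError_(f"{path}: duplicate sample ids: {dups}")
    df = pd.read_csv(path, sep=delim, index_col=0)
    if df.empty:
        raise IOError_(f"{path}: no data rows")
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        raise IOError_(
            f"{path}: non-numeric value {bad.iloc[0]!r} for gene {bad.index[0]!r} "
            f"in sample {col!r}"
        )
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        logger.warning("%s: duplicate gene rows collapsed by mean: %s", path, dups)
        df = df.groupby(level=0, sort=False).mean()
    df.index.name = "gene_id"
    return validate_expression(df)


def read_table(path: PathLike, index_col=0, delimiter: Optional[str] = None) -> pd.DataFrame:
    """Read a generic TSV/CSV table (clinical, scores, variants, cells, masks)."""
    path = Path(path)
    delim = delimiter or _sniff_delimiter(path)
    return pd.read_csv(path, sep=delim, index_col=index_col)


def read_clinical(
    path: PathLike, time_col: str = "time", event_col: str = "event"
) -> pd.DataFrame:
    """Read a clinical table indexed by sample id with time/event columns."""
    df = read_table(path)
    for col in (time_col, event_col):
        if col not in df.columns:
            raise IOError_(f"{path}: missing required column {col!r}")
    return df.rename(columns={time_col: "time", event_col: "event"})


def write_table(df: pd.DataFrame, path: PathLike, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=index)
    return path
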