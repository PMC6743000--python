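"""Tabular I/O for the pipeline's delimiter-separated schemas."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .collagen import COLLAGEN_COLUMNS
from .seasonal import TOOTH_COLUMNS

__all__ = ["read_table", "read_tooth_table", "read_collagen_table", "write_table"]


def read_table(path) -> pd.DataFrame:
    """Read a CSV/TSV (by suffix) or Excel table."""
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        return pd.read_excel(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def _require(df: pd.DataFrame, columns, what: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table missing columns: {missing}")
    return df


def read_tooth_table(path) -> pd.DataFrame:
    """Enamel-band table: one row per 1 mm band, positions in mm from cervix."""
    return _require(read_table(path), TOOTH_COLUMNS, "enamel-band")


def read_collagen_table(path) -> pd.DataFrame:
    return _require(read_table(path), COLLAGEN_COLUMNS, "collagen")


def write_table(df: pd.DataFrame, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df.to_csv(path, sep=sep, index=False)
    return path
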