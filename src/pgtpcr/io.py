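"""Readers and writers for the pipeline's tabular formats.

All tables are plain CSV (TSV for the GeneMapper-style fragment peak table)
with fixed, documented headers; see the ``*_SCHEMA`` constants.  Readers
validate the header and cell types and report offending 1-based data-row
numbers; unknown extra columns are accepted with a warning so lightly
decorated instrument exports still parse.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from .config import LOCI

__all__ = [
    "TableFormatError",
    "TRUTH_SCHEMA", "DETECTIONS_SCHEMA", "MELT_SCHEMA", "PEAKS_SCHEMA",
    "CT_SCHEMA", "MELT_CALLS_SCHEMA",
    "read_table", "write_table",
    "read_truth", "read_detections", "read_melt", "read_peaks", "read_ct",
    "read_melt_calls", "detections_wide",
]


class TableFormatError(ValueError):
    """Raised for missing columns, unparsable cells or empty input files."""


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}

# column -> type tag ("str" | "int" | "float" | "bool")
TRUTH_SCHEMA: Dict[str, str] = {
    "embryo_id": "str", "sex": "str", "x_copies": "int", "y_copies": "int",
    "chr18_copies": "int", "chr21_copies": "int",
    "xx_male_translocation": "bool", "wga_failed": "bool",
}
DETECTIONS_SCHEMA: Dict[str, str] = {"embryo_id": "str",
                                     **{locus: "bool" for locus in LOCI}}
MELT_SCHEMA: Dict[str, str] = {"embryo_id": "str", "gene": "str",
                               "temperature_c": "float", "fluorescence": "float"}
PEAKS_SCHEMA: Dict[str, str] = {"embryo_id": "str", "size_bp": "float",
                                "height_rfu": "float"}
CT_SCHEMA: Dict[str, str] = {"embryo_id": "str", "gene": "str",
                             "input_ng": "float", "ct": "float"}
MELT_CALLS_SCHEMA: Dict[str, str] = {"embryo_id": "str", "gene": "str",
                                     "detected": "bool",
                                     "tm_observed": "float", "qc_pass": "bool"}


def _convert(series: pd.Series, kind: str, col: str) -> pd.Series:
    if kind == "str":
        return series.astype(str)
    raw = series.astype(str).str.strip()
    if kind == "bool":
        low = raw.str.lower()
        bad = ~(low.isin(_TRUE) | low.isin(_FALSE) | (low == "") | (low == "nan"))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise TableFormatError(
                f"column {col!r}: unparsable boolean {raw.iloc[row - 1]!r} at row {row}")
        return low.isin(_TRUE)
    numeric = pd.to_numeric(raw.replace({"": None, "nan": None}), errors="coerce")
    bad = numeric.isna() & ~raw.isin(["", "nan"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise TableFormatError(
            f"column {col!r}: unparsable numeric {raw.iloc[row - 1]!r} at row {row}")
    if kind == "int":
        if numeric.notna().all() and not np.allclose(numeric, numeric.round()):
            row = int(np.flatnonzero(~np.isclose(numeric, numeric.round()))[0]) + 1
            raise TableFormatError(
                f"column {col!r}: non-integer value at row {row}")
        return numeric.astype("Int64").astype("int64") if numeric.notna().all() \
            else numeric
    return numeric.astype(float)


def read_table(path, schema: Dict[str, str], sep: str = ",") -> pd.DataFrame:
    """Read and validate a delimited table against a column schema.

    Missing schema columns, unparsable cells (reported with their 1-based
    data-row number) and empty files raise :class:`TableFormatError`; extra
    columns are kept with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"empty file: {path}") from None
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in schema]
    if extra:
        warnings.warn(f"{path}: ignoring schema for extra columns {extra}",
                      stacklevel=2)
    for col, kind in schema.items():
        df[col] = _convert(df[col], kind, col)
    return df


def write_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)


def read_truth(path) -> pd.DataFrame:
    return read_table(path, TRUTH_SCHEMA)


def read_detections(path) -> pd.DataFrame:
    return read_table(path, DETECTIONS_SCHEMA)


def read_melt(path) -> pd.DataFrame:
    return read_table(path, MELT_SCHEMA)


def read_peaks(path) -> pd.DataFrame:
    """Fragment-analysis peak table (tab-delimited, GeneMapper-export-like)."""
    return read_table(path, PEAKS_SCHEMA, sep="\t")


def read_ct(path) -> pd.DataFrame:
    df = read_table(path, CT_SCHEMA)
    bad = df["ct"].notna() & ((df["ct"] <= 0) | (df["ct"] > 45))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise TableFormatError(f"ct outside (0, 45] at row {row}")
    return df


def read_melt_calls(path) -> pd.DataFrame:
    return read_table(path, MELT_CALLS_SCHEMA)


def detections_wide(melt_calls: pd.DataFrame) -> pd.DataFrame:
    """Pivot per-gene melt calls to one boolean column per locus.

    ``qc_pass`` maps onto the GAPDH column (a QC-failed sample behaves as
    GAPDH-negative downstream).
    """
    wide = (melt_calls.pivot_table(index="embryo_id", columns="gene",
                                   values="detected", aggfunc="last")
            .fillna(False).astype(bool).reset_index())
    qc = melt_calls.groupby("embryo_id")["qc_pass"].all()
    if "GAPDH" in wide.columns:
        wide["GAPDH"] = wide["GAPDH"] & wide["embryo_id"].map(qc).fillna(True)
    else:
        wide["GAPDH"] = wide["embryo_id"].map(qc).fillna(True)
    wide.columns.name = None
    return wide
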