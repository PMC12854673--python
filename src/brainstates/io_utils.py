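"""Tabular readers and writers (TSV first, CSV accepted).

All matrices are written row-major time x entity with a header row;
floats use full precision (%.17g) so write-then-read round trips are
bit-exact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .slds_model import RoiTimeSeries
from .synthetic_data import ParadigmTimeSeries

__all__ = [
    "read_roi_table",
    "write_roi_table",
    "read_paradigm",
    "write_paradigm",
    "write_matrix",
    "write_encoding",
]

_FLOAT_FMT = "%.17g"


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    # round_trip parsing so write-then-read is bit-exact
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_roi_table(path) -> RoiTimeSeries:
    """Read a time x region table; first row is the region names."""
    sep = "," if str(path).endswith(".csv") else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate ROI names: {dupes}")
    df = _read_table(path)
    df.columns = header
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.values.any():
        r, c = np.argwhere(bad.values)[0]
        raise ValueError(f"non-numeric or missing value at row {r}, "
                         f"roi '{df.columns[c]}'")
    return RoiTimeSeries(Y=numeric.values, roi_names=list(df.columns))


def write_roi_table(ts: RoiTimeSeries, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    pd.DataFrame(ts.Y, columns=ts.roi_names).to_csv(
        path, sep=sep, index=False, float_format=_FLOAT_FMT)


def read_paradigm(path) -> ParadigmTimeSeries:
    """Read a paradigm trace (time_s, proximity, direction, shock)."""
    df = _read_table(path)
    required = ["time_s", "proximity", "direction", "shock"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"paradigm file lacks columns: {missing}")
    numeric = df[required].apply(pd.to_numeric, errors="coerce")
    if numeric.isna().values.any():
        r, c = np.argwhere(numeric.isna().values)[0]
        raise ValueError(f"non-numeric value at row {r}, column "
                         f"'{required[c]}'")
    prox = numeric["proximity"].values
    bad = np.nonzero((prox < 0) | (prox > 1))[0]
    if bad.size:
        raise ValueError(f"proximity outside [0, 1] at row {int(bad[0])}: "
                         f"{prox[bad[0]]}")
    return ParadigmTimeSeries(time=numeric["time_s"].values, proximity=prox,
                              direction=numeric["direction"].values.astype(int),
                              shock=numeric["shock"].values.astype(int))


def write_paradigm(par: ParadigmTimeSeries, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    pd.DataFrame({"time_s": par.time, "proximity": par.proximity,
                  "direction": par.direction, "shock": par.shock}).to_csv(
        path, sep=sep, index=False, float_format=_FLOAT_FMT)


def write_matrix(path, values, row_labels=None, col_labels=None) -> None:
    """Generic labelled matrix writer (TSV)."""
    values = np.atleast_2d(np.asarray(values))
    df = pd.DataFrame(values)
    if col_labels is not None:
        df.columns = list(col_labels)
    if row_labels is not None:
        df.index = list(row_labels)
    df.to_csv(path, sep="\t", index=row_labels is not None,
              float_format=_FLOAT_FMT)


def write_encoding(enc, path) -> None:
    """One-hot stimulus matrix as T x M of {0,1} with category header."""
    pd.DataFrame(enc.U.astype(int), columns=enc.category_labels).to_csv(
        path, sep="\t", index=False)
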