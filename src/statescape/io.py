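"""Delimited-text I/O for time series, parameter archives and reports."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ising import MEMParameters

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "save_params",
    "load_params",
    "read_subjects_table",
]


def read_timeseries(path) -> pd.DataFrame:
    """Read a T x N delimited time-series file (header row = ROI names)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.isna().any().any():
        raise ValueError(f"missing values in {path}")
    return df


def write_timeseries(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def save_params(params: MEMParameters, out_dir, stem: str = "mem") -> None:
    """Write h as a one-column table and J as an ROI-named matrix."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.Series(params.h, index=params.roi_names, name="h").to_csv(out / f"{stem}_h.csv")
    pd.DataFrame(params.J, index=params.roi_names, columns=params.roi_names).to_csv(
        out / f"{stem}_J.csv"
    )


def load_params(out_dir, stem: str = "mem") -> MEMParameters:
    out = Path(out_dir)
    h = pd.read_csv(out / f"{stem}_h.csv", index_col=0)["h"]
    J = pd.read_csv(out / f"{stem}_J.csv", index_col=0)
    return MEMParameters(h=h.to_numpy(), J=J.to_numpy(), roi_names=list(h.index))


def read_subjects_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"subject_id", "group"}
    if not required <= set(df.columns):
        raise ValueError(f"subjects table must have columns {sorted(required)}")
    return df
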