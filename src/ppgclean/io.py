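"""Delimited-text readers/writers for PPG records.

Two dialects are supported, both with a mandatory header row:

* two-channel: columns ``t,red,ir``
* single-channel: columns ``t,signal``

The sampling rate is either passed explicitly or inferred from the ``t``
column; when both are available the explicit value wins, and a disagreement
larger than 0.1 % is an error.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .timeseries import TimeSeries, TwoChannelPPG

__all__ = [
    "read_ppg_csv",
    "read_signal_csv",
    "write_ppg_csv",
    "write_signal_csv",
]

_FS_MISMATCH_TOL = 1e-3  # 0.1 %


def _resolve_fs(t: np.ndarray, fs: float | None) -> float:
    dt = np.diff(t)
    if dt.size == 0 or np.any(dt <= 0):
        inferred = None
    else:
        inferred = 1.0 / float(np.median(dt))
    if fs is not None:
        if inferred is not None and abs(inferred - fs) / fs > _FS_MISMATCH_TOL:
            raise ValueError(
                f"explicit fs={fs} Hz disagrees with time column "
                f"(inferred {inferred:.6g} Hz) by more than 0.1%"
            )
        return float(fs)
    if inferred is None:
        raise ValueError("cannot infer fs from time column; pass fs explicitly")
    return inferred


def read_ppg_csv(path: str | Path, fs: float | None = None) -> TwoChannelPPG:
    """Read a two-channel record with columns ``t,red,ir``."""
    df = pd.read_csv(path)
    missing = {"t", "red", "ir"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    rate = _resolve_fs(df["t"].to_numpy(float), fs)
    return TwoChannelPPG(
        red=TimeSeries(df["red"].to_numpy(float), rate),
        ir=TimeSeries(df["ir"].to_numpy(float), rate),
    )


def read_signal_csv(path: str | Path, fs: float | None = None) -> TimeSeries:
    """Read a single-channel record with columns ``t,signal``."""
    df = pd.read_csv(path)
    missing = {"t", "signal"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    rate = _resolve_fs(df["t"].to_numpy(float), fs)
    return TimeSeries(df["signal"].to_numpy(float), rate)


def write_ppg_csv(path: str | Path, ppg: TwoChannelPPG) -> None:
    pd.DataFrame(
        {"t": ppg.red.t, "red": ppg.red.samples, "ir": ppg.ir.samples}
    ).to_csv(path, index=False)


def write_signal_csv(path: str | Path, ts: TimeSeries) -> None:
    pd.DataFrame({"t": ts.t, "signal": ts.samples}).to_csv(path, index=False)
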