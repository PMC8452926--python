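"""Delimited-text formats for feature tables and multichannel EEG segments.

Feature tables are CSV with header ``trial,t,label,f1,...,fN`` — one row per
sliding-window sample.  EEG segments are CSV (channels as columns) preceded
by a comment header carrying the sampling rate, e.g. ``# fs=256``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

META_COLUMNS = ("trial", "t", "label")


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature columns (everything after trial/t/label)."""
    return [c for c in table.columns if c not in META_COLUMNS]


def feature_matrix(table: pd.DataFrame) -> np.ndarray:
    """Feature values as a float array of shape (samples, features)."""
    return table[feature_columns(table)].to_numpy(dtype=float)


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    return table


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_eeg(path) -> tuple[pd.DataFrame, float]:
    """Read a multichannel EEG segment; returns (channels table, fs in Hz)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
    if not header.startswith("#") or "fs=" not in header:
        raise ValueError("EEG file must start with a '# fs=<Hz>' header line")
    fs = float(header.split("fs=")[1].split()[0])
    signal = pd.read_csv(path, comment=None, skiprows=1)
    return signal, fs


def write_eeg(signal: pd.DataFrame, fs: float, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={fs}\n")
        signal.to_csv(fh, index=False)
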