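"""Sliding-window PSDA and CCA feature extraction from multichannel EEG.

A deliberately small front end: re-reference channels, cut 1 s windows every
0.125 s, and per window compute (a) periodogram powers at the first three
harmonics of each candidate stimulus frequency plus their sum (PSDA) and
(b) the largest canonical correlation against sine/cosine references at
those harmonics (CCA).  Per-target feature blocks are reduced to one value
per class as signed distances to one-vs-rest LDA decision borders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "SignalWindow",
    "preprocess_rereference",
    "sliding_windows",
    "psda_features",
    "cca_features",
    "combine_features_lda",
    "extract_feature_table",
]


@dataclass(frozen=True)
class SignalWindow:
    """One window of multichannel EEG: samples (channels, time), fs, start time."""

    samples: np.ndarray
    fs: float
    t0: float

    def __post_init__(self):
        s = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        object.__setattr__(self, "samples", s)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def preprocess_rereference(
    signal: pd.DataFrame, reference_channel: str, target_channels
) -> pd.DataFrame:
    """Subtract the reference channel from each target channel (e.g. Cz from O1/O2)."""
    missing = [c for c in [reference_channel, *target_channels] if c not in signal.columns]
    if missing:
        raise ValueError(f"channels not present: {missing}")
    out = signal.copy()
    for ch in target_channels:
        out[ch] = signal[ch] - signal[reference_channel]
    return out


def sliding_windows(signal: pd.DataFrame, fs: float, w: float = 1.0, step: float = 0.125):
    """Windows of length w at t0 = 0, step, 2*step, ...; count floor((T-w)/step)+1."""
    data = signal.to_numpy(dtype=float).T  # (channels, time)
    n_w = int(round(w * fs))
    n_step = step * fs
    total = data.shape[1]
    if total < n_w:
        import warnings

        warnings.warn("signal shorter than one window; no windows produced", stacklevel=2)
        return []
    n_windows = int(np.floor((total - n_w) / n_step)) + 1
    windows = []
    for k in range(n_windows):
        start = int(round(k * n_step))
        windows.append(SignalWindow(samples=data[:, start : start + n_w], fs=fs, t0=start / fs))
    return windows


def psda_features(window: SignalWindow, target_freq: float, n_harmonics: int = 3) -> np.ndarray:
    """Periodogram powers at the first harmonics of the target, plus their sum.

    Power is read from the periodogram bin nearest each harmonic (rectangular
    window, 'spectrum' scaling), averaged over channels; returns
    ``n_harmonics + 1`` values.
    """
    if target_freq * n_harmonics >= window.fs / 2:
        raise ValueError("harmonics exceed the Nyquist frequency")
    freqs, pxx = sp_signal.periodogram(
        window.samples, fs=window.fs, window="boxcar", scaling="spectrum", axis=-1
    )
    pxx = pxx.mean(axis=0)  # average power over channels
    powers = np.empty(n_harmonics + 1)
    for h in range(n_harmonics):
        idx = int(np.argmin(np.abs(freqs - target_freq * (h + 1))))
        powers[h] = pxx[idx]
    powers[-1] = powers[:-1].sum()
    return powers


def _reference_set(n_samples: int, fs: float, target_freq: float, n_harmonics: int) -> np.ndarray:
    t = np.arange(n_samples) / fs
    cols = []
    for h in range(1, n_harmonics + 1):
        cols.append(np.sin(2 * np.pi * target_freq * h * t))
        cols.append(np.cos(2 * np.pi * target_freq * h * t))
    return np.column_stack(cols)


def cca_features(window: SignalWindow, target_freq: float, n_harmonics: int = 3) -> float:
    """Largest canonical correlation with sine/cosine references at the harmonics.

    Computed directly as the top singular value of Qx^T Qy after QR-
    orthonormalising the centred channel matrix and the 2*n_harmonics
    reference columns; lies in [0, 1].
    """
    if target_freq * n_harmonics >= window.fs / 2:
        raise ValueError("harmonics exceed the Nyquist frequency")
    x = window.samples.T - window.samples.T.mean(axis=0)
    if np.allclose(x, 0.0):
        raise ValueError("constant signal; canonical correlation undefined")
    y = _reference_set(window.n_samples, window.fs, target_freq, n_harmonics)
    y = y - y.mean(axis=0)
    qx = _orthonormal_basis(x)
    qy = _orthonormal_basis(y)
    corr = np.linalg.svd(qx.T @ qy, compute_uv=False)
    return float(np.clip(corr[0], 0.0, 1.0))


def _orthonormal_basis(m: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the column space, dropping near-null directions.

    Rank-deficient inputs (e.g. duplicated channels) would otherwise
    contribute numerical-noise directions that correlate spuriously.
    """
    u, s, _ = np.linalg.svd(m, full_matrices=False)
    keep = s > rtol * s[0]
    return u[:, keep]


def combine_features_lda(blocks: np.ndarray, labels, apply_to: np.ndarray | None = None):
    """Reduce per-target feature blocks to one value per class via LDA.

    For each class a one-vs-rest linear discriminant is fitted on the
    training block matrix (samples x raw features); the output feature is
    the signed distance to that class's decision border.  Returns
    (train_features, applied_features_or_None); shapes (samples, classes).
    """
    blocks = np.asarray(blocks, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    out_train = np.empty((blocks.shape[0], classes.size))
    out_apply = None if apply_to is None else np.empty((len(apply_to), classes.size))
    for k, c in enumerate(classes):
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        lda.fit(blocks, (labels == c).astype(int))
        norm = np.linalg.norm(lda.coef_)
        norm = norm if norm > 0 else 1.0
        out_train[:, k] = lda.decision_function(blocks) / norm
        if apply_to is not None:
            out_apply[:, k] = lda.decision_function(apply_to) / norm
    return out_train, out_apply


def extract_feature_table(
    eeg: pd.DataFrame,
    fs: float,
    stimulus_freqs,
    trial: int = 0,
    w: float = 1.0,
    step: float = 0.125,
    n_harmonics: int = 3,
    label=None,
) -> pd.DataFrame:
    """Raw PSDA + CCA features for every sliding window of one trial.

    Emits one row per window with columns trial, t, label and, per stimulus
    frequency, the PSDA harmonic powers/sum and the CCA correlation
    (``psda<f>_h1.. , psda<f>_sum, cca<f>``).  These raw blocks are the
    input to :func:`combine_features_lda`.
    """
    windows = sliding_windows(eeg, fs, w=w, step=step)
    rows = []
    for win in windows:
        row = {"trial": trial, "t": win.t0, "label": label}
        for f in stimulus_freqs:
            p = psda_features(win, f, n_harmonics=n_harmonics)
            for h in range(n_harmonics):
                row[f"psda{f}_h{h + 1}"] = p[h]
            row[f"psda{f}_sum"] = p[-1]
            row[f"cca{f}"] = cca_features(win, f, n_harmonics=n_harmonics)
        rows.append(row)
    return pd.DataFrame(rows)
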