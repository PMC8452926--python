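"""Synthetic data with the statistical structure the classifier assumes.

Feature tables: one real-valued feature per class, drawn from skew-normal
distributions that are conditionally independent given the class.  Under
class ``i`` the matching feature's location is raised by a separation
``delta`` (in feature units), emulating the SSVEP property that the
attended frequency's feature is elevated.  ``boost_map`` can redirect the
boost to a non-matching feature — the classification method itself does not
rely on "largest feature = correct class".

EEG segments: sums of sinusoids at a target frequency's first harmonics
plus seeded 1/f noise, for exercising the PSDA/CCA front end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SyntheticConfig", "generate_features", "generate_ssvep_eeg"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic feature generator.

    Defaults: 3 classes, skew-normal(location 0, scale 1, shape 3) features,
    separation delta = 2 scale units (a moderately easy problem), and 560
    sliding-window samples per class over 5 trials — 112 windows per trial,
    matching a 15 s stimulation trial scanned with a 1 s window every
    0.125 s.
    """

    n_classes: int = 3
    location: float = 0.0
    scale: float = 1.0
    shape: float = 3.0
    delta: float = 2.0
    samples_per_class: int = 560
    trials_per_class: int = 5
    w: float = 1.0
    s: float = 0.125
    seed: int = 0
    boost_map: tuple | None = None  # class index -> boosted feature index

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.samples_per_class < 1 or self.trials_per_class < 1:
            raise ValueError("need at least one sample and one trial per class")
        if self.samples_per_class % self.trials_per_class:
            raise ValueError("samples_per_class must divide evenly into trials")
        if self.boost_map is not None and len(self.boost_map) != self.n_classes:
            raise ValueError("boost_map must give one feature per class")


def generate_features(cfg: SyntheticConfig) -> pd.DataFrame:
    """Labelled feature table (columns trial, t, label, f1..fN), seeded.

    Features are drawn independently per feature given the class
    (conditional independence holds by construction); rows carry trial ids
    for trial-wise cross-validation and within-trial time stamps.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_classes
    boost = cfg.boost_map if cfg.boost_map is not None else tuple(range(n))
    per_trial = cfg.samples_per_class // cfg.trials_per_class
    rows = {"trial": [], "t": [], "label": []}
    feats = {f"f{i + 1}": [] for i in range(n)}
    for c in range(n):
        for trial in range(cfg.trials_per_class):
            rows["trial"].extend([trial] * per_trial)
            rows["t"].extend((cfg.w + cfg.s * np.arange(per_trial)).tolist())
            rows["label"].extend([c] * per_trial)
            for i in range(n):
                loc = cfg.location + (cfg.delta if boost[c] == i else 0.0)
                draws = stats.skewnorm.rvs(
                    cfg.shape, loc=loc, scale=cfg.scale, size=per_trial, random_state=rng
                )
                feats[f"f{i + 1}"].extend(draws.tolist())
    return pd.DataFrame({**rows, **feats})


def generate_ssvep_eeg(
    target_freq: float,
    n_harmonics: int = 3,
    amplitudes=None,
    noise_level: float = 1.0,
    fs: float = 256.0,
    duration: float = 15.0,
    n_channels: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Multichannel sinusoid-plus-1/f-noise EEG segment, seeded.

    Each channel carries sinusoids at the first ``n_harmonics`` multiples of
    ``target_freq`` (amplitudes default to 1, 0.5, 0.25, ...) with random
    phases shared across channels, plus independent 1/f noise scaled by
    ``noise_level``.  Returns (channels table, fs).
    """
    if fs <= 2.0 * target_freq * n_harmonics:
        raise ValueError("sampling rate must exceed twice the highest harmonic")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration * fs))
    t = np.arange(n_samples) / fs
    if amplitudes is None:
        amplitudes = [2.0**-h for h in range(n_harmonics)]
    amplitudes = np.asarray(amplitudes, dtype=float)
    phases = rng.uniform(0, 2 * np.pi, size=n_harmonics)
    signal = np.zeros(n_samples)
    for h in range(n_harmonics):
        signal += amplitudes[h] * np.sin(2 * np.pi * target_freq * (h + 1) * t + phases[h])
    data = {}
    for ch in range(n_channels):
        data[f"ch{ch + 1}"] = signal + noise_level * _pink_noise(n_samples, rng)
    return pd.DataFrame(data), fs


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    weights = np.ones_like(freqs)
    weights[1:] = 1.0 / np.sqrt(freqs[1:])
    weights[0] = 0.0  # no DC drift
    noise = np.fft.irfft(spectrum * weights, n=n)
    std = noise.std()
    return noise / std if std > 0 else noise
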