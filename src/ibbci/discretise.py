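"""Discretisation of continuous features into per-class bin probabilities.

Each feature gets equal-width bins spanning its training range.  The number
of bins comes from the Freedman-Diaconis or Sturges estimator applied to
each class-conditional sample separately, averaged over classes and rounded
to the nearest integer (halves up).  Per-class bin probabilities
P(B_i = b | C_k) are then estimated either by counting (histogram) or by
fitting a skew-normal distribution per (feature, class) and differencing its
CDF at the bin edges, with the open tails absorbed into the extreme bins so
each row is exactly a probability distribution.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ibbci.io import feature_columns

__all__ = [
    "BinningSpec",
    "ConditionalFeatureModel",
    "fd_bin_count",
    "sturges_bin_count",
    "build_binning",
    "assign_bin",
    "histogram_probs",
    "skewnormal_probs",
]

logger = logging.getLogger(__name__)


def fd_bin_count(samples) -> int:
    """Number of equal-width bins by the Freedman-Diaconis rule.

    Bin width 2*IQR/n^(1/3); count = ceil(range / width).  Degenerate
    inputs fall back: zero range -> 1 bin; zero IQR -> Sturges' count.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 1:
        raise ValueError("need at least one sample")
    rng = float(x.max() - x.min())
    if rng == 0.0:
        return 1
    iqr = float(np.percentile(x, 75) - np.percentile(x, 25))
    if iqr == 0.0:
        return sturges_bin_count(n)
    width = 2.0 * iqr / n ** (1.0 / 3.0)
    return max(int(math.ceil(rng / width)), 1)


def sturges_bin_count(n: int) -> int:
    """Sturges' bin count ceil(log2 n) + 1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return int(math.ceil(math.log2(n))) + 1


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class BinningSpec:
    """Equal-width bin edges per feature; first/last edge = training min/max."""

    edges: tuple  # tuple of np.ndarray, one per feature
    method: str = "histogram"  # probability-estimation method tag

    def __post_init__(self):
        edges = tuple(np.asarray(e, dtype=float) for e in self.edges)
        for e in edges:
            if e.size < 2:
                raise ValueError("each feature needs at least 2 bin edges")
            if np.any(np.diff(e) <= 0):
                raise ValueError("bin edges must be strictly increasing")
        object.__setattr__(self, "edges", edges)

    @property
    def n_features(self) -> int:
        return len(self.edges)

    @property
    def n_bins(self) -> tuple:
        return tuple(e.size - 1 for e in self.edges)

    def to_dict(self) -> dict:
        return {"method": self.method, "edges": [e.tolist() for e in self.edges]}

    @classmethod
    def from_dict(cls, d: dict) -> "BinningSpec":
        return cls(edges=tuple(np.asarray(e) for e in d["edges"]), method=d["method"])


@dataclass(frozen=True)
class ConditionalFeatureModel:
    """Tables P(B_i = b | C_k) per feature i, class k, bin b.

    ``probs[i]`` has shape (n_classes, n_bins_i); ``skew_params[i]`` (when the
    skew-normal method was used) has shape (n_classes, 3) holding the fitted
    (shape, location, scale) per class.
    """

    probs: tuple  # tuple of np.ndarray (n_classes, n_bins_i)
    classes: tuple
    method: str
    skew_params: tuple | None = None

    def __post_init__(self):
        probs = tuple(np.asarray(p, dtype=float) for p in self.probs)
        for p in probs:
            if np.any(p < 0):
                raise ValueError("negative bin probabilities")
            if not np.allclose(p.sum(axis=1), 1.0, rtol=0.0, atol=1e-9):
                raise ValueError("each (feature, class) row must sum to 1")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "classes", tuple(self.classes))

    @property
    def n_features(self) -> int:
        return len(self.probs)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "classes": list(self.classes),
            "probs": [p.tolist() for p in self.probs],
            "skew_params": None
            if self.skew_params is None
            else [p.tolist() for p in self.skew_params],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionalFeatureModel":
        return cls(
            probs=tuple(np.asarray(p) for p in d["probs"]),
            classes=tuple(d["classes"]),
            method=d["method"],
            skew_params=None
            if d.get("skew_params") is None
            else tuple(np.asarray(p) for p in d["skew_params"]),
        )

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


_ESTIMATORS = {"fd": lambda x: fd_bin_count(x), "sturges": lambda x: sturges_bin_count(len(x))}


def build_binning(train: pd.DataFrame, estimator: str = "fd", method: str = "histogram") -> BinningSpec:
    """Equal-width edges per feature from a labelled training table.

    The per-class estimator outputs are averaged (rounded to nearest, halves
    up) to give the bin count; edges span the feature's overall training
    min/max.
    """
    if estimator not in _ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; use 'fd' or 'sturges'")
    count_fn = _ESTIMATORS[estimator]
    classes = sorted(train["label"].unique().tolist())
    if len(classes) < 1:
        raise ValueError("training table has no classes")
    edges = []
    for col in feature_columns(train):
        values = train[col].to_numpy(dtype=float)
        counts = []
        for c in classes:
            sample = train.loc[train["label"] == c, col].to_numpy(dtype=float)
            if sample.size == 0:
                raise ValueError(f"class {c!r} has no samples for feature {col!r}")
            counts.append(count_fn(sample))
        n_bins = max(_round_half_up(float(np.mean(counts))), 1)
        lo, hi = float(values.min()), float(values.max())
        if lo == hi:  # degenerate feature: a single zero-width-avoiding bin
            hi = lo + 1.0
            n_bins = 1
        edges.append(np.linspace(lo, hi, n_bins + 1))
    return BinningSpec(edges=tuple(edges), method=method)


def assign_bin(value, edges) -> np.ndarray | int:
    """Map value(s) to bin indices for half-open bins [l, h).

    The last bin is closed on the right; out-of-range values clamp to the
    first/last bin, so the map is total.
    """
    e = np.asarray(edges, dtype=float)
    idx = np.searchsorted(e, value, side="right") - 1
    idx = np.clip(idx, 0, e.size - 2)
    if np.isscalar(value) or np.ndim(value) == 0:
        return int(idx)
    return idx.astype(np.intp)


def histogram_probs(train: pd.DataFrame, spec: BinningSpec) -> ConditionalFeatureModel:
    """P(B_i = b | C_k) by per-class counting (no smoothing; zeros stay zero)."""
    classes = sorted(train["label"].unique().tolist())
    cols = feature_columns(train)
    if len(cols) != spec.n_features:
        raise ValueError("spec does not match the table's feature count")
    probs = []
    for col, e in zip(cols, spec.edges):
        nb = e.size - 1
        table = np.zeros((len(classes), nb))
        for ki, c in enumerate(classes):
            sample = train.loc[train["label"] == c, col].to_numpy(dtype=float)
            if sample.size == 0:
                raise ValueError(f"class {c!r} has no samples")
            bins = assign_bin(sample, e)
            table[ki] = np.bincount(bins, minlength=nb) / sample.size
        probs.append(table)
    return ConditionalFeatureModel(probs=tuple(probs), classes=tuple(classes), method="histogram")


def skewnormal_probs(train: pd.DataFrame, spec: BinningSpec) -> ConditionalFeatureModel:
    """P(B_i = b | C_k) from maximum-likelihood skew-normal fits per (i, k).

    Interior bins use CDF differences F(h) - F(l); the first and last bin
    absorb the tails (F(h_1) and 1 - F(l_last)) so each row sums to one.
    A fit that fails to converge falls back to a normal fit (shape 0).
    """
    classes = sorted(train["label"].unique().tolist())
    cols = feature_columns(train)
    if len(cols) != spec.n_features:
        raise ValueError("spec does not match the table's feature count")
    probs, params = [], []
    for col, e in zip(cols, spec.edges):
        nb = e.size - 1
        table = np.zeros((len(classes), nb))
        ptab = np.zeros((len(classes), 3))
        for ki, c in enumerate(classes):
            sample = train.loc[train["label"] == c, col].to_numpy(dtype=float)
            if sample.size < 2:
                raise ValueError(f"class {c!r} has too few samples for a fit")
            shape, loc, scale = _fit_skewnormal(sample)
            cdf = stats.skewnorm.cdf(e, shape, loc=loc, scale=scale)
            row = np.diff(cdf)
            row[0] = cdf[1]  # absorb the lower tail
            row[-1] = 1.0 - cdf[-2]  # absorb the upper tail
            row = np.clip(row, 0.0, None)
            table[ki] = row / row.sum()
            ptab[ki] = (shape, loc, scale)
        probs.append(table)
        params.append(ptab)
    return ConditionalFeatureModel(
        probs=tuple(probs), classes=tuple(classes), method="skew-normal", skew_params=tuple(params)
    )


def _fit_skewnormal(sample: np.ndarray) -> tuple[float, float, float]:
    """MLE skew-normal fit with a normal-fit fallback on non-convergence."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            shape, loc, scale = stats.skewnorm.fit(sample)
        except Exception:  # optimisation failure
            shape = loc = scale = math.nan
    if not (np.isfinite(shape) and np.isfinite(loc) and np.isfinite(scale) and scale > 0):
        logger.warning("skew-normal fit failed; falling back to a normal fit")
        loc, scale = stats.norm.fit(sample)
        shape = 0.0
    return float(shape), float(loc), float(scale)
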