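"""Performance measures: confusion accounting with a reject column, accuracy,
mean detection time (MDT), Wolpaw ITR and mutual-information ITR.

The standard (Wolpaw) ITR assumes a doubly symmetric channel; the
mutual-information variant drops that assumption and scores the classifier
by the empirical I(P;C) between predicted and true class, estimated from
the confusion table.  Abstentions do not enter I(P;C); they cost time
instead, through the expected number of retries in MDT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ibbci.classify import UNCLASSIFIED
from ibbci.ib_core import mutual_information

__all__ = [
    "ConfusionTable",
    "TimingConfig",
    "PerformanceReport",
    "itr_wolpaw",
    "mdt",
    "mi_from_confusion",
    "performance_report",
]


@dataclass(frozen=True)
class ConfusionTable:
    """Counts[true class, predicted class], with a final UNCLASSIFIED column."""

    counts: np.ndarray
    classes: tuple

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[1] != c.shape[0] + 1:
            raise ValueError("counts must have shape (N, N+1)")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if len(self.classes) != c.shape[0]:
            raise ValueError("classes length must equal N")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "classes", tuple(self.classes))

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_classified(self) -> int:
        return int(self.counts[:, :-1].sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts[:, :-1]))

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        if self.classes != other.classes:
            raise ValueError("cannot pool tables over different classes")
        return ConfusionTable(self.counts + other.counts, self.classes)

    @classmethod
    def from_predictions(cls, true, predicted, classes=None) -> "ConfusionTable":
        """Tally (true, predicted) pairs; predictions equal to UNCLASSIFIED
        (or None) go to the reject column."""
        true = list(true)
        predicted = list(predicted)
        if classes is None:
            classes = tuple(sorted(set(true)))
        classes = tuple(classes)
        index = {c: i for i, c in enumerate(classes)}
        n = len(classes)
        counts = np.zeros((n, n + 1), dtype=np.int64)
        for t, p in zip(true, predicted):
            col = n if (p is None or (isinstance(p, str) and p == UNCLASSIFIED)) else index[p]
            counts[index[t], col] += 1
        return cls(counts, classes)


@dataclass(frozen=True)
class TimingConfig:
    """Window length w, step s between feature extractions, gaze-shift time (s)."""

    w: float = 1.0
    s: float = 0.125
    gaze: float = 0.0

    def __post_init__(self):
        if self.w <= 0 or self.s <= 0 or self.gaze < 0:
            raise ValueError("w > 0, s > 0 and gaze >= 0 required")


@dataclass(frozen=True)
class PerformanceReport:
    """One evaluation's scores (ITRs in bits/min, MDT in seconds)."""

    accuracy: float
    p_classified: float
    mdt: float
    itr: float
    itr_mi: float
    i_pc: float
    n_predictions: int

    def to_row(self) -> dict:
        """Row layout mirroring the reported result tables."""
        return {
            "ITR_mi": self.itr_mi,
            "ITR": self.itr,
            "Accuracy": self.accuracy,
            "MDT": self.mdt,
            "No. pred.": self.n_predictions,
        }


def itr_wolpaw(n_classes: int, a: float) -> float:
    """Wolpaw ITR per prediction (bits), for N targets at accuracy a.

    log2 N + a log2 a + (1-a) log2((1-a)/(N-1)); the a -> 0 and a -> 1
    limits use the 0 log 0 = 0 convention.  Negative below chance level.
    """
    if n_classes < 2:
        raise ValueError("need at least two targets")
    if not 0.0 <= a <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    out = np.log2(n_classes)
    if a > 0:
        out += a * np.log2(a)
    if a < 1:
        out += (1 - a) * np.log2((1 - a) / (n_classes - 1))
    return float(out)


def mdt(timing: TimingConfig, p_classified: float) -> float:
    """Mean detection time w + (1/p - 1)*s + gaze, in seconds.

    The step s is charged once per expected failed (rejected) window before
    a successful classification; p = 0 yields an infinite MDT.
    """
    if not 0.0 <= p_classified <= 1.0:
        raise ValueError("p_classified must lie in [0, 1]")
    if p_classified == 0.0:
        return float("inf")
    return timing.w + (1.0 / p_classified - 1.0) * timing.s + timing.gaze


def mi_from_confusion(table: ConfusionTable, include_unclassified: bool = False) -> float:
    """Empirical I(P;C) in bits from a confusion table (plug-in estimate).

    By default the reject column is excluded and the remaining joint is
    renormalised, so I(P;C) measures information per *classified* sample;
    ``include_unclassified=True`` instead treats abstention as an (N+1)-th
    prediction outcome.
    """
    if include_unclassified:
        counts = table.counts.T  # predicted x true
    else:
        if table.n_classified == 0:
            raise ValueError("no classified samples; I(P;C) undefined")
        counts = table.counts[:, :-1].T
    joint = counts / counts.sum()
    return mutual_information(joint)


def performance_report(table: ConfusionTable, timing: TimingConfig) -> PerformanceReport:
    """Accuracy, MDT, Wolpaw ITR and mutual-information ITR for one run."""
    total = table.n_total
    if total == 0:
        raise ValueError("empty confusion table")
    classified = table.n_classified
    p_classified = classified / total
    if classified == 0:
        return PerformanceReport(
            accuracy=float("nan"),
            p_classified=0.0,
            mdt=float("inf"),
            itr=0.0,
            itr_mi=0.0,
            i_pc=0.0,
            n_predictions=0,
        )
    a = table.n_correct / classified
    detection = mdt(timing, p_classified)
    i_pc = mi_from_confusion(table)
    per_min = 60.0 / detection
    return PerformanceReport(
        accuracy=a,
        p_classified=p_classified,
        mdt=detection,
        itr=itr_wolpaw(table.n_classes, a) * per_min,
        itr_mi=i_pc * per_min,
        i_pc=i_pc,
        n_predictions=classified,
    )


def reports_to_frame(reports: dict) -> pd.DataFrame:
    """Stack named PerformanceReports into a result table."""
    return pd.DataFrame({name: r.to_row() for name, r in reports.items()}).T
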