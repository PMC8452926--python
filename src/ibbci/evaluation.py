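"""Cross-validation and parameter scans tying the pipeline together.

Folds are defined by trial id (leave-one-trial-out), never by shuffling
rows: sliding-window samples within a trial are strongly dependent, so
splitting within trials would leak.  ``scan_beta`` tabulates the solver's
information quantities over a grid of beta values; ``scan_t`` sweeps
Classifier 2's vote threshold over its whole valid range for each
neighbourhood radius.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ibbci.classify import (
    Classifier2Config,
    TrainedClassifier,
    fit,
    predict_table,
    valid_t_range,
    vote_counts,
)
from ibbci.ib_core import IBConfig, JointXC, solve_generalized_ib
from ibbci.metrics import (
    ConfusionTable,
    PerformanceReport,
    TimingConfig,
    performance_report,
)

__all__ = ["CVPlan", "CVResult", "cross_validate", "scan_beta", "scan_t"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVPlan:
    """Leave-one-trial-out partition: one fold per trial id."""

    folds: tuple  # tuple of (train_trials, test_trials)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "CVPlan":
        trials = sorted(table["trial"].unique())
        if len(trials) < 2:
            raise ValueError("need at least two trials for cross-validation")
        folds = tuple(
            (tuple(t for t in trials if t != held_out), (held_out,)) for held_out in trials
        )
        return cls(folds=folds)

    @property
    def n_folds(self) -> int:
        return len(self.folds)


@dataclass(frozen=True)
class CVResult:
    """Per-fold and pooled cross-validation outcomes."""

    fold_reports: tuple
    fold_tables: tuple
    pooled_table: ConfusionTable
    pooled: PerformanceReport


def cross_validate(
    table: pd.DataFrame,
    method: str = "skew-normal",
    estimator: str = "fd",
    ib: IBConfig | None = None,
    classifier: Classifier2Config | None = None,
    timing: TimingConfig | None = None,
    tau: float = 1e-6,
    rule: str = "strict",
) -> CVResult:
    """Trial-wise cross-validation of the full training/prediction pipeline.

    ``classifier=None`` evaluates Classifier 1 (the point rule); passing a
    :class:`Classifier2Config` evaluates the neighbourhood-vote rule.
    Pooled metrics are computed on the summed test confusion counts.
    """
    ib = ib or IBConfig()
    timing = timing or TimingConfig()
    plan = CVPlan.from_table(table)
    classes = tuple(sorted(table["label"].unique()))
    fold_reports, fold_tables = [], []
    pooled_counts = None
    for fold_idx, (train_trials, test_trials) in enumerate(plan.folds):
        train = table[table["trial"].isin(train_trials)]
        test = table[table["trial"].isin(test_trials)]
        missing = set(classes) - set(train["label"].unique())
        if missing:
            raise ValueError(f"classes {sorted(missing)} missing from training fold {fold_idx}")
        clf = fit(train, method=method, estimator=estimator, ib=ib, tau=tau, rule=rule)
        preds = predict_table(clf, test, cfg=classifier)
        conf = ConfusionTable.from_predictions(preds["true"], preds["predicted"], classes=classes)
        fold_tables.append(conf)
        fold_reports.append(performance_report(conf, timing))
        pooled_counts = conf if pooled_counts is None else pooled_counts + conf
        logger.info(
            "fold %d: %d/%d classified, accuracy %.3f",
            fold_idx,
            conf.n_classified,
            conf.n_total,
            fold_reports[-1].accuracy,
        )
    return CVResult(
        fold_reports=tuple(fold_reports),
        fold_tables=tuple(fold_tables),
        pooled_table=pooled_counts,
        pooled=performance_report(pooled_counts, timing),
    )


def scan_beta(joint: JointXC, alpha: float, betas=None, config: IBConfig | None = None) -> pd.DataFrame:
    """Solve the bottleneck over a beta grid; tabulate information quantities.

    Default grid 10, 20, ..., 150.  One multi-restart solve per beta; columns
    beta, H_P, I_PX, I_PC, H_P_given_X, n_occupied, objective.
    """
    if betas is None:
        betas = list(range(10, 151, 10))
    config = config or IBConfig()
    rows = []
    for beta in betas:
        sol = solve_generalized_ib(joint, replace(config, alpha=alpha, beta=float(beta)))
        rows.append(
            {
                "beta": beta,
                "H_P": sol.H_P,
                "I_PX": sol.I_PX,
                "I_PC": sol.I_PC,
                "H_P_given_X": sol.H_P_given_X,
                "n_occupied": len(sol.occupied_clusters),
                "objective": sol.objective,
            }
        )
    return pd.DataFrame(rows)


def scan_t(
    clf: TrainedClassifier,
    test: pd.DataFrame,
    n_values=(1, 2, 3, 4),
    timing: TimingConfig | None = None,
) -> pd.DataFrame:
    """Classifier 2 performance over the full valid t range per radius n.

    Vote counts are computed once per n and swept over thresholds; returns
    one row per (n, t) with the usual performance columns.
    """
    timing = timing or TimingConfig()
    classes = clf.classes
    feats = test[[c for c in test.columns if c not in ("trial", "t", "label")]].to_numpy(float)
    true = test["label"].to_numpy()
    rows = []
    for n in n_values:
        counts = vote_counts(clf, feats, n)  # (samples, classes)
        t_min, t_max = valid_t_range(n, clf.n_features)
        for t in range(t_min, t_max + 1):
            reached = counts >= t
            n_reached = reached.sum(axis=1)
            cidx = np.where(n_reached == 1, np.argmax(reached, axis=1), -1)
            predicted = [None if c < 0 else classes[c] for c in cidx]
            conf = ConfusionTable.from_predictions(true, predicted, classes=classes)
            report = performance_report(conf, timing)
            rows.append(
                {
                    "n": n,
                    "t": t,
                    "ITR_mi": report.itr_mi,
                    "ITR": report.itr,
                    "Accuracy": report.accuracy,
                    "MDT": report.mdt,
                    "No. pred.": report.n_predictions,
                    "p_classified": report.p_classified,
                }
            )
    return pd.DataFrame(rows)
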