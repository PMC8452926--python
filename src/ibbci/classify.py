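"""End-to-end training and prediction with a reject option.

Training: discretise features, build the conditionally independent joint
p(x, c), solve the information bottleneck for an encoder q(p|x), then map
the (arbitrarily numbered) clusters of P onto class labels by exhaustive
search over injective mappings, keeping the one with the highest training
accuracy.

Prediction: Classifier 1 outputs the class whose cluster carries (nearly)
all the posterior mass q(p|x) at the sample's bin vector, and abstains
otherwise.  Classifier 2 additionally requires at least ``t`` of the
``(2n+1)^F`` neighbouring bin vectors to be classified the same way,
trading more abstentions for higher accuracy.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ibbci.discretise import (
    BinningSpec,
    ConditionalFeatureModel,
    build_binning,
    histogram_probs,
    skewnormal_probs,
)
from ibbci.ib_core import IBConfig, IBSolution, JointXC, solve_generalized_ib
from ibbci.io import feature_matrix
from ibbci.joint_model import XIndexer, build_joint, sample_to_x

__all__ = [
    "UNCLASSIFIED",
    "AmbiguityError",
    "ClusterMapping",
    "Classifier2Config",
    "TrainedClassifier",
    "fit",
    "map_clusters",
    "predict_c1",
    "predict_c2",
    "predict_table",
    "valid_t_range",
    "vote_counts",
]

#: Sentinel returned when the classifier abstains.
UNCLASSIFIED = "UNCLASSIFIED"


class AmbiguityError(RuntimeError):
    """Two classes exceeded the vote threshold (t below the majority bound)."""


@dataclass(frozen=True)
class ClusterMapping:
    """Injective map from occupied cluster ids to class indices."""

    mapping: dict

    def __post_init__(self):
        m = dict(self.mapping)
        if len(set(m.values())) != len(m):
            raise ValueError("cluster-to-class mapping must be injective")
        object.__setattr__(self, "mapping", m)

    def __getitem__(self, cluster: int) -> int:
        return self.mapping[cluster]

    def get(self, cluster: int, default=None):
        return self.mapping.get(cluster, default)


@dataclass(frozen=True)
class Classifier2Config:
    """Neighbourhood radius ``n`` (bins) and vote threshold ``t`` (cells)."""

    n: int = 1
    t: int = 14

    def __post_init__(self):
        if self.n < 0 or self.t < 1:
            raise ValueError("n must be >= 0 and t >= 1")


def valid_t_range(n: int, n_features: int) -> tuple[int, int]:
    """Valid vote thresholds (t_min, t_max), inclusive.

    t_max = (2n+1)^F (all neighbouring cells agree); t_min is the smallest
    integer strictly above half of t_max, which guarantees at most one class
    can reach the threshold.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    t_max = (2 * n + 1) ** n_features
    t_min = t_max // 2 + 1
    return t_min, t_max


def map_clusters(clusters: np.ndarray, labels: np.ndarray, occupied, n_classes: int) -> ClusterMapping:
    """Best injective cluster -> class-index map by training accuracy.

    ``clusters`` holds each training sample's assigned cluster (-1 when the
    sample was rejected); ``labels`` the true class indices.  All injective
    maps from the occupied clusters into the classes are enumerated; ties
    break to the lexicographically smallest mapping over sorted cluster ids.
    """
    occ = sorted(occupied)
    if len(occ) > n_classes:
        raise ValueError("more occupied clusters than classes; cannot map injectively")
    mask = clusters >= 0
    cl, lb = clusters[mask], labels[mask]
    # correct-count matrix: hits[j, c] = #samples in cluster occ[j] with label c
    hits = np.zeros((len(occ), n_classes))
    for j, p in enumerate(occ):
        sel = cl == p
        if sel.any():
            hits[j] = np.bincount(lb[sel], minlength=n_classes)
    best_map, best_score = None, -1.0
    for perm in itertools.permutations(range(n_classes), len(occ)):
        score = sum(hits[j, c] for j, c in enumerate(perm))
        if score > best_score or (score == best_score and (best_map is None or perm < best_map)):
            best_map, best_score = perm, score
    return ClusterMapping(mapping={p: c for p, c in zip(occ, best_map)})


@dataclass(frozen=True)
class TrainedClassifier:
    """All fitted state needed to classify a feature vector."""

    spec: BinningSpec
    model: ConditionalFeatureModel
    indexer: XIndexer
    joint: JointXC
    solution: IBSolution
    mapping: ClusterMapping
    classes: tuple
    tau: float = 1e-6
    rule: str = "strict"  # "strict" (posterior ~ 1) or "argmax"
    cell_class: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.model.n_classes != len(self.classes):
            raise ValueError("model/classes mismatch")
        if self.indexer.n_x != self.joint.n_x:
            raise ValueError("indexer/joint mismatch")
        if self.cell_class is None:
            object.__setattr__(self, "cell_class", _cell_classes(self))

    @property
    def n_features(self) -> int:
        return self.spec.n_features

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "model": self.model.to_dict(),
            "solution": self.solution.to_dict(),
            "joint": {
                "p_xc": self.joint.p_xc.tolist(),
                "x_support": self.joint.x_support.tolist(),
                "pmin": self.joint.pmin,
            },
            "mapping": {str(k): v for k, v in self.mapping.mapping.items()},
            "classes": list(self.classes),
            "tau": self.tau,
            "rule": self.rule,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedClassifier":
        spec = BinningSpec.from_dict(d["spec"])
        return cls(
            spec=spec,
            model=ConditionalFeatureModel.from_dict(d["model"]),
            indexer=XIndexer.from_spec(spec),
            joint=JointXC(
                p_xc=np.asarray(d["joint"]["p_xc"]),
                x_support=np.asarray(d["joint"]["x_support"], dtype=np.intp),
                pmin=d["joint"]["pmin"],
            ),
            solution=IBSolution.from_dict(d["solution"]),
            mapping=ClusterMapping({int(k): v for k, v in d["mapping"].items()}),
            classes=tuple(d["classes"]),
            tau=d["tau"],
            rule=d["rule"],
        )

    @classmethod
    def from_json(cls, s: str) -> "TrainedClassifier":
        return cls.from_dict(json.loads(s))


def _cell_clusters(solution: IBSolution, joint: JointXC, tau: float, rule: str) -> np.ndarray:
    """Cluster id per full-grid cell (-1 = rejected / outside the support)."""
    out = np.full(joint.n_x, -1, dtype=np.intp)
    enc = solution.encoder
    if rule == "argmax":
        clusters = np.argmax(enc, axis=1)
    elif rule == "strict":
        clusters = np.where(enc.max(axis=1) >= 1.0 - tau, np.argmax(enc, axis=1), -1)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    out[joint.x_support] = clusters
    return out


def _cell_classes(clf: "TrainedClassifier") -> np.ndarray:
    """Class index per full-grid cell (-1 = unclassified)."""
    cells = _cell_clusters(clf.solution, clf.joint, clf.tau, clf.rule)
    out = np.full(cells.size, -1, dtype=np.intp)
    for cluster, cidx in clf.mapping.mapping.items():
        out[cells == cluster] = cidx
    return out


def fit(
    train: pd.DataFrame,
    method: str = "skew-normal",
    estimator: str = "fd",
    ib: IBConfig | None = None,
    prior: str = "empirical",
    tau: float = 1e-6,
    rule: str = "strict",
) -> TrainedClassifier:
    """Train the full pipeline on a labelled feature table.

    ``method`` selects histogram or skew-normal bin probabilities,
    ``estimator`` the bin-count rule (Freedman-Diaconis or Sturges), and
    ``prior`` the class prior ("empirical" frequencies or "uniform").
    """
    ib = ib or IBConfig()
    classes = tuple(sorted(train["label"].unique().tolist()))
    if len(classes) < 2:
        raise ValueError("need at least two classes to train")
    spec = build_binning(train, estimator=estimator, method=method)
    if method == "histogram":
        model = histogram_probs(train, spec)
    elif method == "skew-normal":
        model = skewnormal_probs(train, spec)
    else:
        raise ValueError(f"unknown method {method!r}")
    if prior == "empirical":
        counts = train["label"].value_counts()
        prior_vec = np.array([counts[c] for c in classes], dtype=float)
        prior_vec /= prior_vec.sum()
    elif prior == "uniform":
        prior_vec = np.full(len(classes), 1.0 / len(classes))
    else:
        raise ValueError(f"unknown prior {prior!r}")
    indexer = XIndexer.from_spec(spec)
    joint = build_joint(model, prior=prior_vec, pmin=ib.pmin)
    if ib.n_clusters is None:
        ib = IBConfig(**{**ib.__dict__, "n_clusters": len(classes)})
    solution = solve_generalized_ib(joint, ib)

    # per-training-sample cluster under the classification rule
    cells = _cell_clusters(solution, joint, tau, rule)
    x_flat = sample_to_x(feature_matrix(train), spec, indexer)
    sample_clusters = cells[np.atleast_1d(x_flat)]
    label_idx = np.array([classes.index(l) for l in train["label"]])
    mapping = map_clusters(sample_clusters, label_idx, solution.occupied_clusters, len(classes))
    return TrainedClassifier(
        spec=spec,
        model=model,
        indexer=indexer,
        joint=joint,
        solution=solution,
        mapping=mapping,
        classes=classes,
        tau=tau,
        rule=rule,
    )


def predict_c1(clf: TrainedClassifier, features):
    """Point rule: class of the sample's bin vector, or UNCLASSIFIED."""
    vec = np.asarray(features, dtype=float)
    if vec.ndim != 1 or vec.size != clf.n_features:
        raise ValueError("feature vector length does not match the classifier")
    x = sample_to_x(vec, clf.spec, clf.indexer)
    cidx = clf.cell_class[x]
    return UNCLASSIFIED if cidx < 0 else clf.classes[cidx]


def vote_counts(clf: TrainedClassifier, features, n: int) -> np.ndarray:
    """Per-class neighbourhood vote counts for each sample.

    For every offset tuple in {-n..n}^F the shifted bin vector is looked up
    (offsets leaving the bin grid count for no class) and its class, if any,
    receives one vote.  Returns an integer array (samples, classes).
    """
    arr = np.atleast_2d(np.asarray(features, dtype=float))
    n_feat = clf.n_features
    bins = clf.indexer.decode(np.atleast_1d(sample_to_x(arr, clf.spec, clf.indexer)))
    offsets = np.stack(
        np.meshgrid(*[np.arange(-n, n + 1)] * n_feat, indexing="ij"), axis=-1
    ).reshape(-1, n_feat)
    shifted = bins[:, None, :] + offsets[None, :, :]  # (S, M, F)
    nb = np.asarray(clf.indexer.n_bins)
    valid = np.all((shifted >= 0) & (shifted < nb), axis=-1)  # (S, M)
    strides = np.concatenate([np.cumprod(nb[::-1])[::-1][1:], [1]])  # row-major
    flat = (np.where(valid[..., None], shifted, 0) * strides).sum(axis=-1)
    cell = np.where(valid, clf.cell_class[flat], -1)  # (S, M)
    counts = np.stack(
        [(cell == c).sum(axis=1) for c in range(len(clf.classes))], axis=1
    )
    return counts


def predict_c2(clf: TrainedClassifier, features, cfg: Classifier2Config):
    """Neighbourhood vote rule: a class needs at least ``t`` agreeing cells.

    With ``t`` above half the neighbourhood size at most one class can reach
    the threshold; a lower ``t`` may produce a tie, which raises
    AmbiguityError.
    """
    t_min, t_max = valid_t_range(cfg.n, clf.n_features)
    if not t_min <= cfg.t <= t_max:
        warnings.warn(
            f"t={cfg.t} outside the valid range [{t_min}, {t_max}] for n={cfg.n}",
            stacklevel=2,
        )
    counts = vote_counts(clf, np.atleast_2d(np.asarray(features, dtype=float)), cfg.n)[0]
    winners = np.flatnonzero(counts >= cfg.t)
    if winners.size > 1:
        raise AmbiguityError(f"classes {winners.tolist()} all reached t={cfg.t}")
    return UNCLASSIFIED if winners.size == 0 else clf.classes[int(winners[0])]


def predict_table(
    clf: TrainedClassifier, table: pd.DataFrame, cfg: Classifier2Config | None = None
) -> pd.DataFrame:
    """Predict every row of a feature table (Classifier 1, or 2 when cfg given).

    Returns a table with columns trial, t, true, predicted (UNCLASSIFIED for
    abstentions).
    """
    feats = feature_matrix(table)
    if cfg is None:
        x = np.atleast_1d(sample_to_x(feats, clf.spec, clf.indexer))
        cidx = clf.cell_class[x]
    else:
        counts = vote_counts(clf, feats, cfg.n)
        reached = counts >= cfg.t
        n_reached = reached.sum(axis=1)
        if np.any(n_reached > 1):
            raise AmbiguityError("multiple classes reached the vote threshold")
        cidx = np.where(n_reached == 1, np.argmax(reached, axis=1), -1)
    predicted = [UNCLASSIFIED if c < 0 else clf.classes[c] for c in cidx]
    return pd.DataFrame(
        {
            "trial": table["trial"].to_numpy(),
            "t": table["t"].to_numpy(),
            "true": table["label"].to_numpy(),
            "predicted": predicted,
        }
    )
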