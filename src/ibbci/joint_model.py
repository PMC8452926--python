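"""Joint distribution over the bin vector X = (B_1, ..., B_F) and class C.

Per-feature bin probabilities are combined under the assumption that the
binned features are conditionally independent given the class:

    p(x, c) = p(c) * prod_i P(B_i = b_i | C = c)

The bin-vector tuples are flattened to integer indices by a row-major
mixed-radix encoding (first feature most significant), which is what the
information-bottleneck solver consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ibbci.discretise import BinningSpec, ConditionalFeatureModel, assign_bin
from ibbci.ib_core import JointXC, SizeGuardError, _as_prob_array

__all__ = ["XIndexer", "build_joint", "sample_to_x"]

MAX_CELLS = 10**6  # dense-grid cap; the state space grows exponentially in features


@dataclass(frozen=True)
class XIndexer:
    """Bijection between bin-vector tuples and flat row-major indices."""

    n_bins: tuple  # bins per feature

    def __post_init__(self):
        nb = tuple(int(b) for b in self.n_bins)
        if any(b < 1 for b in nb):
            raise ValueError("every feature needs at least one bin")
        object.__setattr__(self, "n_bins", nb)

    @property
    def n_x(self) -> int:
        return int(np.prod(self.n_bins))

    def encode(self, bins) -> np.ndarray | int:
        """Bin tuple(s) -> flat index; first feature is most significant."""
        arr = np.asarray(bins, dtype=np.intp)
        scalar = arr.ndim == 1
        flat = np.ravel_multi_index(np.atleast_2d(arr).T, self.n_bins)
        return int(flat[0]) if scalar else flat

    def decode(self, index) -> np.ndarray:
        """Flat index(es) -> bin tuple(s)."""
        out = np.stack(np.unravel_index(np.asarray(index, dtype=np.intp), self.n_bins), axis=-1)
        return out

    @classmethod
    def from_spec(cls, spec: BinningSpec) -> "XIndexer":
        return cls(n_bins=spec.n_bins)


def build_joint(
    model: ConditionalFeatureModel,
    prior=None,
    pmin: float = 1e-12,
    max_cells: int = MAX_CELLS,
) -> JointXC:
    """Assemble p(x, c) from per-feature conditionals and a class prior.

    ``prior`` defaults to uniform over the model's classes.  Rows whose
    marginal p(x) falls below ``pmin`` are excluded from the support (the
    classifier later rejects samples landing there).
    """
    n_classes = model.n_classes
    if prior is None:
        prior = np.full(n_classes, 1.0 / n_classes)
    prior = _as_prob_array(prior).ravel()
    if prior.size != n_classes:
        raise ValueError("prior length must equal the number of classes")
    n_bins = tuple(p.shape[1] for p in model.probs)
    n_x = int(np.prod(n_bins))
    if n_x > max_cells:
        raise SizeGuardError(
            f"bin grid has {n_x} cells (> {max_cells}); the dense state space "
            "grows exponentially with the number of classes/features"
        )
    # p(x|c) per class by an outer product over features, flattened in C order
    # to match XIndexer's row-major encoding.
    p_xc = np.empty((n_x, n_classes))
    for c in range(n_classes):
        acc = model.probs[0][c]
        for p in model.probs[1:]:
            acc = np.multiply.outer(acc, p[c])
        p_xc[:, c] = acc.ravel(order="C") * prior[c]
    return JointXC.from_full(p_xc, pmin=pmin)


def sample_to_x(features, spec: BinningSpec, indexer: XIndexer | None = None):
    """Feature vector(s) -> flat bin-vector index (bin per feature, then encode)."""
    if indexer is None:
        indexer = XIndexer.from_spec(spec)
    raw = np.asarray(features, dtype=float)
    scalar = raw.ndim == 1
    arr = np.atleast_2d(raw)
    if arr.shape[1] != spec.n_features:
        raise ValueError("feature vector length does not match the binning spec")
    bins = np.column_stack(
        [assign_bin(arr[:, i], spec.edges[i]) for i in range(spec.n_features)]
    )
    flat = indexer.encode(bins)
    return int(flat[0]) if scalar else flat
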