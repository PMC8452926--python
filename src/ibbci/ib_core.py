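"""Information-theoretic primitives and the generalized information bottleneck.

The information bottleneck (IB) compresses a random variable ``X`` (here the
vector of binned feature values) into a representation ``P`` (the predicted
class) while preserving information about a relevance variable ``C`` (the
true class).  The generalized objective interpolates, via ``alpha``, between
the original IB (``alpha = 1``, compression cost ``I(P;X)``) and the
deterministic IB (``alpha = 0``, representational cost ``H(P)``):

    minimise  H(P) - alpha * H(P|X) - beta * I(P;C)

over conditional distributions ``q(p|x)``, subject to the Markov chain
``C -> X -> P``.  For ``alpha = 0`` the optimal encoder is a deterministic
function of ``X``, which is what makes the solution directly usable as a
classification rule.  All logarithms are base 2; all information quantities
are in bits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiscreteDistribution",
    "JointXC",
    "IBConfig",
    "IBSolution",
    "InvalidDistributionError",
    "DegenerateInputError",
    "SizeGuardError",
    "entropy",
    "conditional_entropy",
    "mutual_information",
    "solve_generalized_ib",
    "ib_objective",
    "exhaustive_dib_oracle",
]

_ATOL_SUM = 1e-9
_TINY = 1e-300  # clamp for log arguments; log2(1e-300) ~ -996


class InvalidDistributionError(ValueError):
    """Raised when probabilities are negative or do not sum to one."""


class DegenerateInputError(ValueError):
    """Raised when an input carries no usable probability mass."""


class SizeGuardError(ValueError):
    """Raised when an exhaustive computation would be infeasibly large."""


def _as_prob_array(probs, atol: float = 1e-12) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.size == 0:
        raise InvalidDistributionError("empty probability table")
    if np.any(p < 0):
        raise InvalidDistributionError("negative probability entries")
    total = p.sum()
    if not np.isclose(total, 1.0, rtol=0.0, atol=atol):
        raise InvalidDistributionError(f"probabilities sum to {total!r}, not 1")
    return p


@dataclass(frozen=True)
class DiscreteDistribution:
    """A finite probability distribution (non-negative, sums to one)."""

    probs: np.ndarray
    labels: tuple | None = None

    def __post_init__(self):
        p = _as_prob_array(self.probs).ravel()
        object.__setattr__(self, "probs", p)
        if self.labels is not None:
            labels = tuple(self.labels)
            if len(labels) != p.size:
                raise ValueError("labels length must match number of outcomes")
            object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return self.probs.size


def _entropy_bits(p: np.ndarray) -> float:
    """Shannon entropy in bits with the 0 log 0 = 0 convention."""
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def entropy(dist) -> float:
    """Entropy H(Y) in bits of a distribution (array-like or DiscreteDistribution)."""
    if isinstance(dist, DiscreteDistribution):
        p = dist.probs
    else:
        p = _as_prob_array(dist).ravel()
    return _entropy_bits(p)


def conditional_entropy(joint) -> float:
    """Conditional entropy H(Y|Z) = H(Y,Z) - H(Z) from a joint table p(y, z)."""
    p = _as_prob_array(joint)
    if p.ndim != 2:
        raise InvalidDistributionError("joint must be a 2-D table")
    return _entropy_bits(p.ravel()) - _entropy_bits(p.sum(axis=0))


def mutual_information(joint) -> float:
    """Mutual information I(Y;Z) = H(Y) - H(Y|Z) in bits from a joint table.

    Clamped at zero: the plug-in estimate can dip a few ulp negative.
    """
    p = _as_prob_array(joint)
    if p.ndim != 2:
        raise InvalidDistributionError("joint must be a 2-D table")
    h_y = _entropy_bits(p.sum(axis=1))
    h_z = _entropy_bits(p.sum(axis=0))
    h_yz = _entropy_bits(p.ravel())
    return max(h_y + h_z - h_yz, 0.0)


@dataclass(frozen=True)
class JointXC:
    """Joint distribution p(x, c) over the flattened bin-vector index and class.

    ``p_xc`` covers the full bin grid; ``x_support`` lists the rows whose
    marginal p(x) is at least ``pmin``.  Rows outside the support are treated
    as unclassifiable downstream (the reject option's "filtered out" states).
    """

    p_xc: np.ndarray
    x_support: np.ndarray
    pmin: float

    def __post_init__(self):
        p = np.asarray(self.p_xc, dtype=float)
        if p.ndim != 2:
            raise InvalidDistributionError("p_xc must be 2-D [|X| x N]")
        if np.any(p < 0):
            raise InvalidDistributionError("negative joint probabilities")
        if not np.isclose(p.sum(), 1.0, rtol=0.0, atol=_ATOL_SUM):
            raise InvalidDistributionError("joint must sum to 1 within 1e-9")
        support = np.asarray(self.x_support, dtype=np.intp)
        if support.size and np.any(p[support].sum(axis=1) < self.pmin):
            raise InvalidDistributionError("retained x with marginal below pmin")
        object.__setattr__(self, "p_xc", p)
        object.__setattr__(self, "x_support", support)

    @classmethod
    def from_full(cls, p_xc, pmin: float = 1e-12) -> "JointXC":
        """Build from a full joint table, filtering rows with p(x) < pmin."""
        p = np.asarray(p_xc, dtype=float)
        support = np.flatnonzero(p.sum(axis=1) >= pmin)
        return cls(p_xc=p, x_support=support, pmin=pmin)

    @property
    def n_classes(self) -> int:
        return self.p_xc.shape[1]

    @property
    def n_x(self) -> int:
        return self.p_xc.shape[0]

    def support_joint(self) -> np.ndarray:
        """Joint restricted to the retained x rows, renormalised."""
        if self.x_support.size == 0:
            raise DegenerateInputError("empty support after filtering")
        p = self.p_xc[self.x_support]
        return p / p.sum()

    def mi_xc(self) -> float:
        """I(X;C) of the (support-restricted, renormalised) joint, in bits."""
        return mutual_information(self.support_joint())


@dataclass(frozen=True)
class IBConfig:
    """Configuration of the generalized IB solver.

    alpha interpolates between deterministic IB (0) and original IB (1);
    beta weighs I(P;C) preservation against compression; n_clusters is the
    allowed cardinality of P (defaults to the number of classes).
    """

    alpha: float = 1.0
    beta: float = 100.0
    n_clusters: int | None = None
    max_iter: int = 1000
    tol: float = 1e-8
    restarts: int = 20
    seed: int = 0
    pmin: float = 1e-12

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.n_clusters is not None and self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1 or self.restarts < 1:
            raise ValueError("max_iter and restarts must be >= 1")


@dataclass(frozen=True)
class IBSolution:
    """Converged encoder q(p|x) with its induced quantities (all in bits).

    The encoder rows are indexed by position within the joint's ``x_support``;
    filtered-out x values have no row and predict "no assignment".
    """

    encoder: np.ndarray
    marginal: np.ndarray
    decoder: np.ndarray
    objective: float
    H_P: float
    H_P_given_X: float
    I_PX: float
    I_PC: float
    occupied_clusters: frozenset
    alpha: float
    beta: float
    n_iter: int = 0
    converged: bool = True
    objective_history: tuple = field(default=(), repr=False)

    @property
    def n_clusters(self) -> int:
        return self.encoder.shape[1]

    def hard_assignment(self) -> np.ndarray:
        """Per-x cluster by argmax of the encoder row (ties -> lowest index)."""
        return np.argmax(self.encoder, axis=1)

    def to_dict(self) -> dict:
        return {
            "encoder": self.encoder.tolist(),
            "marginal": self.marginal.tolist(),
            "decoder": self.decoder.tolist(),
            "objective": self.objective,
            "H_P": self.H_P,
            "H_P_given_X": self.H_P_given_X,
            "I_PX": self.I_PX,
            "I_PC": self.I_PC,
            "occupied_clusters": sorted(self.occupied_clusters),
            "alpha": self.alpha,
            "beta": self.beta,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "IBSolution":
        return cls(
            encoder=np.asarray(d["encoder"], dtype=float),
            marginal=np.asarray(d["marginal"], dtype=float),
            decoder=np.asarray(d["decoder"], dtype=float),
            objective=d["objective"],
            H_P=d["H_P"],
            H_P_given_X=d["H_P_given_X"],
            I_PX=d["I_PX"],
            I_PC=d["I_PC"],
            occupied_clusters=frozenset(d["occupied_clusters"]),
            alpha=d["alpha"],
            beta=d["beta"],
            n_iter=d.get("n_iter", 0),
            converged=d.get("converged", True),
        )

    @classmethod
    def from_json(cls, s: str) -> "IBSolution":
        return cls.from_dict(json.loads(s))


def _support_pieces(joint: JointXC):
    """p(x), p(c|x) over the renormalised support rows."""
    pj = joint.support_joint()
    p_x = pj.sum(axis=1)
    p_c_given_x = pj / p_x[:, None]
    return p_x, p_c_given_x


def _quantities(p_x, p_c_given_x, encoder, alpha, beta):
    """Marginal, decoder and information quantities induced by an encoder."""
    q_p = p_x @ encoder
    # joint q(p, c) under the Markov chain C -> X -> P
    q_pc = (encoder * p_x[:, None]).T @ p_c_given_x
    with np.errstate(divide="ignore", invalid="ignore"):
        decoder = np.where(q_p[:, None] > 0, q_pc / np.maximum(q_p, _TINY)[:, None], 0.0)
    h_p = _entropy_bits(q_p)
    row_ent = -np.where(encoder > 0, encoder * np.log2(np.maximum(encoder, _TINY)), 0.0).sum(axis=1)
    h_p_given_x = float(p_x @ row_ent)
    i_pc = mutual_information(q_pc / q_pc.sum())
    i_px = max(h_p - h_p_given_x, 0.0)
    objective = h_p - alpha * h_p_given_x - beta * i_pc
    return q_p, decoder, h_p, h_p_given_x, i_px, i_pc, objective


def _scores(q_p, decoder, p_c_given_x, beta):
    """Per-(x, p) score log2 q(p) - beta * KL(p(c|x) || q(c|p)), in bits.

    Empty clusters (q(p) = 0) and decoder zeros where p(c|x) > 0 get hugely
    negative scores via clamping, so they are never (re)selected.
    """
    log_qp = np.log2(np.maximum(q_p, _TINY))
    log_dec = np.log2(np.maximum(decoder, _TINY))
    neg_h = np.where(
        p_c_given_x > 0, p_c_given_x * np.log2(np.maximum(p_c_given_x, _TINY)), 0.0
    ).sum(axis=1)
    cross = p_c_given_x @ log_dec.T  # (|X|, k)
    kl = neg_h[:, None] - cross
    return log_qp[None, :] - beta * kl


def _one_hot(assignment: np.ndarray, k: int) -> np.ndarray:
    enc = np.zeros((assignment.size, k))
    enc[np.arange(assignment.size), assignment] = 1.0
    return enc


def solve_generalized_ib(joint: JointXC, config: IBConfig) -> IBSolution:
    """Solve min H(P) - alpha*H(P|X) - beta*I(P;C) by self-consistent iteration.

    Runs ``config.restarts`` seeded random initialisations and returns the
    solution with the lowest objective.  For ``alpha = 0`` the update is the
    hard argmax of the score (deterministic encoder, ties to the lowest
    cluster index); for ``alpha > 0`` encoder rows are the softmax of the
    score divided by alpha.  Convergence: |delta objective| < tol, or
    max_iter reached.
    """
    if joint.x_support.size == 0:
        raise DegenerateInputError("empty support after filtering")
    k = config.n_clusters if config.n_clusters is not None else joint.n_classes
    p_x, p_c_given_x = _support_pieces(joint)
    n_x = p_x.size
    master = np.random.default_rng(config.seed)
    best: IBSolution | None = None

    for _ in range(config.restarts):
        rng = np.random.default_rng(master.integers(0, 2**31))
        if config.alpha == 0.0:
            encoder = _one_hot(rng.integers(0, k, size=n_x), k)
        else:
            encoder = rng.dirichlet(np.ones(k), size=n_x)
        q_p, decoder, *_, objective = _quantities(p_x, p_c_given_x, encoder, config.alpha, config.beta)
        history = [objective]
        converged = False
        for _it in range(config.max_iter):
            score = _scores(q_p, decoder, p_c_given_x, config.beta)
            if config.alpha == 0.0:
                encoder = _one_hot(np.argmax(score, axis=1), k)
            else:
                logits = score * (np.log(2.0) / config.alpha)
                logits -= logits.max(axis=1, keepdims=True)
                encoder = np.exp(logits)
                encoder /= encoder.sum(axis=1, keepdims=True)
            q_p, decoder, h_p, h_px, i_px, i_pc, new_obj = _quantities(
                p_x, p_c_given_x, encoder, config.alpha, config.beta
            )
            history.append(new_obj)
            if abs(new_obj - objective) < config.tol:
                objective = new_obj
                converged = True
                break
            objective = new_obj
        else:
            q_p, decoder, h_p, h_px, i_px, i_pc, objective = _quantities(
                p_x, p_c_given_x, encoder, config.alpha, config.beta
            )
        if config.alpha == 0.0:
            h_px = 0.0  # deterministic encoder, exactly
        sol = IBSolution(
            encoder=encoder,
            marginal=q_p,
            decoder=decoder,
            objective=objective,
            H_P=h_p,
            H_P_given_X=h_px,
            I_PX=i_px,
            I_PC=i_pc,
            occupied_clusters=frozenset(np.flatnonzero(q_p > 1e-12).tolist()),
            alpha=config.alpha,
            beta=config.beta,
            n_iter=len(history) - 1,
            converged=converged,
            objective_history=tuple(history),
        )
        if best is None or sol.objective < best.objective:
            best = sol
    return best


def ib_objective(solution: IBSolution, alpha: float, beta: float) -> float:
    """Generalized objective H(P) - alpha*H(P|X) - beta*I(P;C), in bits."""
    return solution.H_P - alpha * solution.H_P_given_X - beta * solution.I_PC


def exhaustive_dib_oracle(joint: JointXC, beta: float, n_clusters: int) -> IBSolution:
    """Globally optimal deterministic encoder by enumerating every hard map.

    Enumerates all ``n_clusters ** |x_support|`` deterministic assignments of
    retained x values to clusters and returns the minimiser of
    H(P) - beta*I(P;C).  Intended as an independent test oracle for the
    iterative alpha = 0 solver; guarded to small instances.
    """
    n_x = int(joint.x_support.size)
    if n_x == 0:
        raise DegenerateInputError("empty support after filtering")
    if n_x > 12 or n_clusters > 3:
        raise SizeGuardError("exhaustive enumeration limited to |X| <= 12, k <= 3")
    if beta <= 0:
        raise ValueError("beta must be positive")
    p_x, p_c_given_x = _support_pieces(joint)
    pj = joint.support_joint()  # (n_x, N)
    k = n_clusters
    m = k**n_x
    radix = k ** np.arange(n_x - 1, -1, -1)
    assignments = (np.arange(m)[:, None] // radix[None, :]) % k  # (m, n_x)
    # q(p, c) for every assignment
    q_pc = np.empty((m, k, pj.shape[1]))
    for j in range(k):
        q_pc[:, j, :] = (assignments == j).astype(float) @ pj
    q_p = q_pc.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_p = -np.where(q_p > 0, q_p * np.log2(np.maximum(q_p, _TINY)), 0.0).sum(axis=1)
        h_pc = -np.where(q_pc > 0, q_pc * np.log2(np.maximum(q_pc, _TINY)), 0.0).sum(axis=(1, 2))
    h_c = _entropy_bits(pj.sum(axis=0))
    i_pc = h_p + h_c - h_pc
    objective = h_p - beta * i_pc
    ibest = int(np.argmin(objective))
    encoder = _one_hot(assignments[ibest], k)
    q_p_b, decoder, h_p_b, h_px_b, i_px_b, i_pc_b, obj_b = _quantities(
        p_x, p_c_given_x, encoder, 0.0, beta
    )
    return IBSolution(
        encoder=encoder,
        marginal=q_p_b,
        decoder=decoder,
        objective=obj_b,
        H_P=h_p_b,
        H_P_given_X=0.0,
        I_PX=i_px_b,
        I_PC=i_pc_b,
        occupied_clusters=frozenset(np.flatnonzero(q_p_b > 1e-12).tolist()),
        alpha=0.0,
        beta=beta,
    )
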