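import numpy as np
import pytest

from ibbci.classify import fit
from ibbci.ib_core import IBConfig
from ibbci.synthetic import SyntheticConfig, generate_features


def doubly_symmetric_joint(n: int, a: float) -> np.ndarray:
    """Joint p(y, z) of a doubly symmetric channel with uniform marginals."""
    off = (1.0 - a) / (n - 1)
    joint = np.full((n, n), off / n)
    np.fill_diagonal(joint, a / n)
    return joint


def wolpaw_closed_form(n: int, a: float) -> float:
    """Independent closed-form evaluation of the symmetric-channel capacity."""
    out = np.log2(n)
    if a > 0:
        out += a * np.log2(a)
    if a < 1:
        out += (1 - a) * np.log2((1 - a) / (n - 1))
    return float(out)


@pytest.fixture(scope="session")
def easy_table():
    """Well-separated 3-class synthetic features (delta = 10 scale units)."""
    return generate_features(SyntheticConfig(delta=10.0, samples_per_class=200, seed=11))


@pytest.fixture(scope="session")
def noisy_table():
    """Moderately noisy 3-class synthetic features (delta = 1.5 scale units)."""
    return generate_features(SyntheticConfig(delta=1.5, samples_per_class=200, seed=12))


@pytest.fixture(scope="session")
def easy_clf(easy_table):
    """Classifier trained on the well-separated table (alpha = 1, beta = 100)."""
    return fit(easy_table, ib=IBConfig(restarts=5, seed=13))


@pytest.fixture(scope="session")
def noisy_clf(noisy_table):
    train = noisy_table[noisy_table["trial"] != 4]
    return fit(train, ib=IBConfig(restarts=5, seed=14))
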