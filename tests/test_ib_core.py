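"""Information primitives and the generalized/deterministic IB solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from conftest import doubly_symmetric_joint, wolpaw_closed_form
from ibbci.ib_core import (
    DiscreteDistribution,
    IBConfig,
    IBSolution,
    InvalidDistributionError,
    JointXC,
    SizeGuardError,
    conditional_entropy,
    entropy,
    exhaustive_dib_oracle,
    ib_objective,
    mutual_information,
    solve_generalized_ib,
)


def random_joint(rng, n_x, n_c):
    return rng.dirichlet(np.ones(n_x * n_c)).reshape(n_x, n_c)


joints = hnp.arrays(
    np.float64, (5, 3), elements=st.floats(0.01, 1.0, allow_nan=False)
).map(lambda a: a / a.sum())


class TestEntropy:
    @pytest.mark.parametrize(
        "probs,expected",
        [
            ((0.25, 0.25, 0.25, 0.25), 2.0),
            ((1.0, 0.0, 0.0), 0.0),
            ((0.5, 0.25, 0.25), 1.5),
        ],
    )
    def test_closed_forms(self, probs, expected):
        assert entropy(probs) == pytest.approx(expected, abs=1e-12)
        assert entropy(DiscreteDistribution(np.array(probs))) == pytest.approx(expected)

    def test_invalid_distributions_rejected(self):
        with pytest.raises(InvalidDistributionError):
            entropy([0.5, 0.6])
        with pytest.raises(InvalidDistributionError):
            entropy([-0.5, 1.5])
        with pytest.raises(InvalidDistributionError):
            DiscreteDistribution(np.array([0.3, 0.3]))


class TestConditionalEntropyAndMI:
    def test_identity_joint_determines_y(self):
        assert conditional_entropy(np.eye(3) / 3) == pytest.approx(0.0, abs=1e-12)

    def test_independent_uniform(self):
        joint = np.full((2, 2), 0.25)
        assert conditional_entropy(joint) == pytest.approx(1.0, abs=1e-12)
        assert mutual_information(joint) == pytest.approx(0.0, abs=1e-12)

    def test_doubly_symmetric_matches_channel_capacity_form(self):
        # H(Y|Z) = H(Y) - I where I has the closed symmetric-channel form
        joint = doubly_symmetric_joint(3, 0.9)
        expected_i = wolpaw_closed_form(3, 0.9)
        assert mutual_information(joint) == pytest.approx(expected_i, abs=1e-12)
        assert conditional_entropy(joint) == pytest.approx(np.log2(3) - expected_i, abs=1e-12)

    def test_deterministic_channel(self):
        assert mutual_information(np.eye(3) / 3) == pytest.approx(np.log2(3), abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(joints)
    def test_mi_symmetric_nonnegative_bounded(self, joint):
        i = mutual_information(joint)
        assert i == pytest.approx(mutual_information(joint.T), abs=1e-12)
        assert i >= 0.0
        h_y = entropy(joint.sum(axis=1))
        h_z = entropy(joint.sum(axis=0))
        assert i <= min(h_y, h_z) + 1e-12


class TestJointXC:
    def test_filtering_and_support(self):
        p = np.array([[0.5, 0.3], [0.2, 0.0], [0.0, 0.0]])
        joint = JointXC.from_full(p, pmin=1e-6)
        assert joint.x_support.tolist() == [0, 1]
        assert joint.support_joint().sum() == pytest.approx(1.0)

    def test_invalid_total_rejected(self):
        with pytest.raises(InvalidDistributionError):
            JointXC.from_full(np.array([[0.5, 0.4]]))


class TestSolver:
    def test_no_class_information_collapses_to_one_cluster(self):
        # identical p(c|x) rows: nothing to preserve, H(P) cost wins
        p_c = np.array([0.2, 0.3, 0.5])
        p_xc = np.outer(np.full(4, 0.25), p_c)
        joint = JointXC.from_full(p_xc)
        sol = solve_generalized_ib(joint, IBConfig(alpha=0.0, beta=100.0, n_clusters=3, seed=0))
        assert len(sol.occupied_clusters) == 1
        assert sol.I_PC == pytest.approx(0.0, abs=1e-9)
        assert sol.H_P == pytest.approx(0.0, abs=1e-9)

    def test_dib_encoder_rows_one_hot(self):
        rng = np.random.default_rng(0)
        joint = JointXC.from_full(random_joint(rng, 8, 3))
        sol = solve_generalized_ib(joint, IBConfig(alpha=0.0, beta=100.0, n_clusters=3, seed=1))
        assert np.all(np.isin(sol.encoder, (0.0, 1.0)))
        assert sol.H_P_given_X == 0.0

    def test_matches_exhaustive_oracle_on_small_instance(self):
        rng = np.random.default_rng(42)
        joint = JointXC.from_full(random_joint(rng, 8, 3))
        sol = solve_generalized_ib(
            joint, IBConfig(alpha=0.0, beta=100.0, n_clusters=3, restarts=50, seed=2)
        )
        oracle = exhaustive_dib_oracle(joint, beta=100.0, n_clusters=3)
        assert sol.objective == pytest.approx(oracle.objective, abs=1e-9)

    def test_encoder_rows_on_simplex_alpha_one(self):
        rng = np.random.default_rng(3)
        joint = JointXC.from_full(random_joint(rng, 10, 3))
        sol = solve_generalized_ib(joint, IBConfig(alpha=1.0, beta=50.0, n_clusters=3, seed=3))
        assert np.allclose(sol.encoder.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(sol.encoder >= 0)

    def test_objective_history_non_increasing(self):
        rng = np.random.default_rng(4)
        joint = JointXC.from_full(random_joint(rng, 10, 3))
        for alpha in (0.0, 0.5, 1.0):
            sol = solve_generalized_ib(
                joint, IBConfig(alpha=alpha, beta=30.0, n_clusters=3, restarts=3, seed=5)
            )
            diffs = np.diff(sol.objective_history)
            assert np.all(diffs <= 1e-9)

    def test_data_processing_inequality(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            joint = JointXC.from_full(random_joint(rng, rng.integers(4, 12), 3))
            for alpha in (0.0, 1.0):
                sol = solve_generalized_ib(
                    joint,
                    IBConfig(alpha=alpha, beta=100.0, n_clusters=3, restarts=5, seed=7),
                )
                assert sol.I_PC <= joint.mi_xc() + 1e-9

    def test_config_validation(self):
        with pytest.raises(ValueError):
            IBConfig(alpha=1.5)
        with pytest.raises(ValueError):
            IBConfig(beta=0.0)
        with pytest.raises(ValueError):
            IBConfig(n_clusters=0)

    def test_empty_support_raises(self):
        p = np.zeros((3, 2))
        p[0, 0] = 1.0
        joint = JointXC(p_xc=p, x_support=np.array([], dtype=np.intp), pmin=1e-12)
        with pytest.raises(Exception):
            solve_generalized_ib(joint, IBConfig(n_clusters=2))


class TestObjective:
    def test_identities(self):
        rng = np.random.default_rng(8)
        joint = JointXC.from_full(random_joint(rng, 8, 3))
        sol = solve_generalized_ib(joint, IBConfig(alpha=1.0, beta=20.0, n_clusters=3, seed=9))
        # alpha=1: H(P) - H(P|X) = I(P;X)
        assert ib_objective(sol, 1.0, 20.0) == pytest.approx(
            sol.I_PX - 20.0 * sol.I_PC, abs=1e-9
        )
        # alpha=0: H(P) - beta I(P;C)
        assert ib_objective(sol, 0.0, 20.0) == pytest.approx(
            sol.H_P - 20.0 * sol.I_PC, abs=1e-12
        )

    def test_single_cluster_solution_is_zero(self):
        p_xc = np.outer(np.full(4, 0.25), [0.5, 0.5])
        joint = JointXC.from_full(p_xc)
        sol = solve_generalized_ib(joint, IBConfig(alpha=0.0, beta=10.0, n_clusters=2, seed=0))
        assert ib_objective(sol, 0.0, 10.0) == pytest.approx(0.0, abs=1e-9)


class TestOracle:
    def test_lossless_encoder_found_when_classes_separate(self):
        # two x values, each carrying one class only
        joint = JointXC.from_full(np.array([[0.5, 0.0], [0.0, 0.5]]))
        sol = exhaustive_dib_oracle(joint, beta=10.0, n_clusters=2)
        assert sol.I_PC == pytest.approx(joint.mi_xc(), abs=1e-12)

    def test_identical_rows_single_cluster(self):
        p_xc = np.outer(np.full(3, 1 / 3), [0.4, 0.6])
        sol = exhaustive_dib_oracle(JointXC.from_full(p_xc), beta=10.0, n_clusters=2)
        assert len(sol.occupied_clusters) == 1

    def test_global_minimum_over_enumeration(self):
        rng = np.random.default_rng(10)
        joint = JointXC.from_full(random_joint(rng, 6, 3))
        oracle = exhaustive_dib_oracle(joint, beta=100.0, n_clusters=3)
        # independent re-enumeration: every deterministic map scores no lower
        pj = joint.support_joint()
        n_x = pj.shape[0]
        for code in range(3**n_x):
            assign = [(code // 3**i) % 3 for i in range(n_x)]
            q_pc = np.zeros((3, 3))
            for x, p in enumerate(assign):
                q_pc[p] += pj[x]
            q_p = q_pc.sum(axis=1)
            obj = entropy(q_p) - 100.0 * mutual_information(q_pc / q_pc.sum())
            assert oracle.objective <= obj + 1e-9

    def test_size_guard(self):
        rng = np.random.default_rng(11)
        joint = JointXC.from_full(random_joint(rng, 13, 3))
        with pytest.raises(SizeGuardError):
            exhaustive_dib_oracle(joint, beta=10.0, n_clusters=3)


def test_solution_json_round_trip():
    rng = np.random.default_rng(12)
    joint = JointXC.from_full(rng.dirichlet(np.ones(24)).reshape(8, 3))
    sol = solve_generalized_ib(joint, IBConfig(alpha=1.0, beta=100.0, n_clusters=3, seed=13))
    back = IBSolution.from_json(sol.to_json())
    assert np.allclose(back.encoder, sol.encoder)
    assert back.objective == pytest.approx(sol.objective)
    assert back.occupied_clusters == sol.occupied_clusters


def test_solver_deterministic_given_seed():
    rng = np.random.default_rng(14)
    joint = JointXC.from_full(random_joint(rng, 9, 3))
    cfg = IBConfig(alpha=1.0, beta=100.0, n_clusters=3, seed=15)
    a = solve_generalized_ib(joint, cfg)
    b = solve_generalized_ib(joint, cfg)
    assert np.array_equal(a.encoder, b.encoder)
    assert a.objective == b.objective
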