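"""Performance index, mixing estimation, convergence, classification."""

import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from anpca.data import DimensionError, EpochSet, Recording
from anpca.metrics import (
    NOT_CONVERGED,
    QualityReport,
    classify_blocks,
    combined_system,
    convergence_epochs,
    estimate_mixing,
    performance_index,
    pi_db,
    pi_from_db,
)
from anpca.preprocess import epoch_extract
from anpca.synth import generate_stimulus_sequence, simulate_session


def _brute_force_pi(C):
    """Independent loop-based reimplementation of the index."""
    M = C.shape[0]
    total = 0.0
    for i in range(M):
        row = np.abs(C[i, :]) ** 2
        col = np.abs(C[:, i]) ** 2
        total += (1 - row.max() / row.sum()) + (1 - col.max() / col.sum())
    return total / (2 * (M - 1))


def _scaled_permutation(n, rng):
    P = np.eye(n)[rng.permutation(n)]
    scales = rng.uniform(0.5, 3.0, size=n) * rng.choice([-1.0, 1.0], size=n)
    return P * scales[:, None]


class TestPerformanceIndex:
    def test_scaled_permutation_is_exactly_zero(self):
        rng = np.random.default_rng(0)
        for n in (2, 3, 5, 8):
            assert performance_index(_scaled_permutation(n, rng)) == 0.0

    def test_all_equal_matrix_is_exactly_one(self):
        for n in (2, 3, 6):
            assert performance_index(np.full((n, n), 0.7)) == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            C = rng.standard_normal((3, 3))
            assert performance_index(C) == pytest.approx(_brute_force_pi(C), rel=1e-12)

    @given(st.integers(0, 10_000))
    def test_value_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        C = rng.standard_normal((4, 4))
        # rows/columns of a continuous random matrix are nonzero a.s.
        pi = performance_index(C)
        assert 0.0 <= pi <= 1.0

    @given(st.integers(0, 10_000))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        C = rng.standard_normal((4, 4))
        Pr = np.eye(4)[rng.permutation(4)]
        Pc = np.eye(4)[rng.permutation(4)]
        assert performance_index(Pr @ C @ Pc) == pytest.approx(
            performance_index(C), rel=1e-12
        )

    @given(st.integers(0, 10_000),
           st.floats(0.01, 100.0, allow_nan=False))
    def test_global_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        C = rng.standard_normal((3, 3))
        assert performance_index(scale * C) == pytest.approx(
            performance_index(C), rel=1e-9
        )

    @given(st.integers(0, 10_000))
    def test_diagonal_scaling_preserves_perfect_separation(self, seed):
        # PI = 0 is stable under arbitrary nonzero row/column scalings
        rng = np.random.default_rng(seed)
        C = _scaled_permutation(4, rng)
        dr = np.diag(rng.uniform(0.1, 5.0, 4))
        dc = np.diag(rng.uniform(0.1, 5.0, 4))
        assert performance_index(dr @ C @ dc) == 0.0

    def test_shape_validation(self):
        with pytest.raises(DimensionError):
            performance_index(np.ones((2, 3)))
        with pytest.raises(DimensionError):
            performance_index(np.ones((1, 1)))

    def test_zero_row_rejected(self):
        C = np.eye(3)
        C[1] = 0.0
        with pytest.raises(ValueError):
            performance_index(C)


class TestDecibels:
    def test_convention_is_20log10(self):
        assert pi_db(0.1) == pytest.approx(-20.0)
        assert pi_db(0.03) == pytest.approx(20 * np.log10(0.03))

    def test_round_trip(self):
        assert pi_from_db(pi_db(0.0123)) == pytest.approx(0.0123, rel=1e-12)

    def test_edge_cases(self):
        assert pi_db(0.0) == -np.inf
        with pytest.raises(ValueError):
            pi_db(-0.1)


class TestCombinedSystem:
    def test_product_and_conformability(self):
        rng = np.random.default_rng(0)
        W, P, V = rng.standard_normal((4, 4)), rng.standard_normal((4, 4)), \
            rng.standard_normal((4, 8))
        assert np.allclose(combined_system(W, P, V), W @ P @ V)
        with pytest.raises(DimensionError):
            combined_system(W, P, V.T)


class TestEstimateMixing:
    def test_recovers_least_squares_solution(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal((3, 3000))
        A = rng.standard_normal((5, 3))
        x = A @ y
        # oracle: the exact least-squares mixing
        A_ls = np.linalg.lstsq(y.T, x.T, rcond=None)[0].T
        state = estimate_mixing(y, x, alpha=0.3, epochs=3)
        assert np.allclose(state.Q, A_ls, atol=1e-6)
        # residual RMS per epoch is non-increasing toward zero
        assert state.residual_trace[-1] < 1e-8
        assert state.n_updates == 3 * 3000

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(DimensionError):
            estimate_mixing(np.zeros((2, 10)), np.zeros((3, 11)))


class TestConvergenceEpochs:
    def test_flat_trajectory_converges_at_one(self):
        assert convergence_epochs(np.full(6, 0.02)) == 1

    def test_settling_point_detected(self):
        traj = np.array([1.0, 0.5, 0.2, 0.1, 0.1001, 0.1001, 0.1001])
        # first epoch from which the next two relative changes are < 1%
        assert convergence_epochs(traj, tol=0.01) == 4

    def test_never_converges(self):
        traj = np.array([1.0, 0.5, 0.25, 0.12, 0.06])
        assert convergence_epochs(traj, tol=0.01) == NOT_CONVERGED

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            convergence_epochs(np.array([0.1]))


class TestClassification:
    def test_perfect_on_clean_erp_source(self):
        rec, sources, model, events = simulate_session(n_blocks=8, seed=3)
        erp = Recording(X=sources.S[:1], fs=256.0, channel_labels=("erp",))
        ep = epoch_extract(erp, events, window=(0.0, 0.7), baseline=(-0.1, 0.0))
        cls = classify_blocks(ep, events)
        assert cls.accuracy == 1.0
        assert all(v == 1.0 for v in cls.accuracy_by_m.values())
        assert np.all(cls.predictions == events.target_id)

    def test_chance_level_without_signal(self):
        events = generate_stimulus_sequence(70, seed=5)
        rng = np.random.default_rng(0)
        noise = rng.standard_normal((len(events), 1, 180))
        ep = EpochSet(data=noise, fs=256.0, window=(0.0, 0.7),
                      baseline=None, events=events)
        cls = classify_blocks(ep, events)
        # pure noise: accuracy near chance (1/7 ~ 0.14) for single blocks
        assert 0.02 < cls.accuracy_by_m[1] < 0.35

    def test_score_window_outside_epoch_rejected(self):
        events = generate_stimulus_sequence(2, seed=0)
        ep = EpochSet(data=np.zeros((len(events), 1, 180)), fs=256.0,
                      window=(0.0, 0.7), baseline=None, events=events)
        with pytest.raises(ValueError):
            classify_blocks(ep, events, score_window=(2.0, 3.0))


class TestQualityReport:
    def test_json_round_trip(self, tmp_path):
        rep = QualityReport(
            C=np.eye(2), pi_final=0.02, pi_db_final=pi_db(0.02),
            pi_iterations=np.array([[50, 0.3], [100, 0.05]]),
            pi_epochs=np.array([0.3, 0.02]), converged_epoch=1, converged=True,
        )
        path = tmp_path / "report.json"
        rep.to_json(path)
        loaded = json.loads(path.read_text())
        assert loaded["pi_final"] == pytest.approx(0.02)
        assert loaded["converged"] is True
        assert rep.first_iteration_below(0.1) == 100
        assert rep.first_iteration_below(0.001) == -1
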