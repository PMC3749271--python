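"""Pre-separation: spatial whitening, delayed-covariance rotation, PC tracking."""

import numpy as np
import pytest
from scipy import signal as sg

from anpca.data import DimensionError, Recording
from anpca.metrics import performance_index
from anpca.preseparation import (
    delayed_rotation,
    pc_cost,
    pc_cost_gradient,
    pre_separate,
    spatial_whiten,
    track_pc,
)


def _ar1(pole: float, n: int, rng) -> np.ndarray:
    x = sg.lfilter([1.0], [1.0, -pole], rng.standard_normal(n + 500))[500:]
    return x / x.std()


class TestSpatialWhiten:
    def test_whitened_covariance_is_identity(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((5, 3))
        X = A @ rng.standard_normal((3, 20000))
        rec = Recording(X=X, fs=256.0, channel_labels=tuple("abcde"))
        B, xb, lam, V = spatial_whiten(rec, n_keep=3)
        R = (xb @ xb.T) / xb.shape[1]
        assert np.allclose(R, np.eye(3), atol=1e-8)
        assert np.all(np.diff(lam) <= 1e-12)  # descending spectrum

    def test_auto_rank_detects_source_count(self, session0):
        B, xb, lam, V = spatial_whiten(session0.rec, n_keep="auto")
        assert B.shape[0] == 4  # 4 noiseless sources in 8 channels

    def test_invalid_n_keep(self):
        rec = Recording(
            X=np.random.default_rng(0).standard_normal((3, 100)),
            fs=256.0, channel_labels=tuple("abc"),
        )
        with pytest.raises(DimensionError):
            spatial_whiten(rec, n_keep=9)

    def test_rank_deficient_request_rejected(self):
        rng = np.random.default_rng(0)
        row = rng.standard_normal(400)
        rec = Recording(X=np.vstack([row, row, row]), fs=256.0,
                        channel_labels=tuple("abc"))
        with pytest.raises(DimensionError, match="rank"):
            spatial_whiten(rec, n_keep=3)

    def test_too_few_samples(self):
        rec = Recording(X=np.zeros((4, 6)) + np.eye(4, 6), fs=256.0,
                        channel_labels=tuple("abcd"))
        with pytest.raises(DimensionError):
            spatial_whiten(rec)


class TestDelayedRotation:
    def test_recovers_rotation_of_distinct_autocorrelations(self):
        rng = np.random.default_rng(0)
        S = np.vstack([_ar1(0.9, 20000, rng), _ar1(-0.5, 20000, rng)])
        S -= S.mean(axis=1, keepdims=True)
        Q, _ = np.linalg.qr(rng.standard_normal((2, 2)))
        V, x_pre, lam, deg = delayed_rotation(Q @ S, tau=1)
        assert not deg
        assert performance_index(V.T @ Q) < 0.01

    def test_degeneracy_flag_on_identical_autocorrelations(self):
        # two white rows share the (zero) lag-1 autocorrelation: the delayed
        # covariance spectrum is degenerate and the flag must be raised
        rng = np.random.default_rng(1)
        W = rng.standard_normal((2, 20000))
        _, _, lam, deg = delayed_rotation(W, tau=1, gap_tol=0.1)
        assert deg
        assert abs(lam[0] - lam[1]) < 0.1

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            delayed_rotation(np.zeros((2, 100)), tau=0)

    def test_signal_shorter_than_delay(self):
        with pytest.raises(DimensionError):
            delayed_rotation(np.zeros((2, 10)), tau=50)


class TestPreSeparate:
    def test_source_recovery_on_session(self, session0):
        state, x_pre = pre_separate(session0.rec, n_keep=4)
        # every band-passed source is recovered by some output with
        # correlation above 0.95 (oracle: ground-truth sources)
        corr = np.corrcoef(np.vstack([x_pre, session0.sources_filtered]))[:4, 4:]
        assert np.all(np.max(np.abs(corr), axis=0) > 0.95)

    def test_v_total_composition(self, session0):
        state, x_pre = pre_separate(session0.rec, n_keep=4)
        X = session0.rec.X - session0.rec.X.mean(axis=1, keepdims=True)
        assert np.allclose(state.V_total @ X, x_pre, atol=1e-8)
        assert state.mixing_estimate.shape == (8, 4)


class TestCostAndGradient:
    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        h = 1e-6
        for _ in range(20):
            v = rng.standard_normal(4)
            x = rng.standard_normal(4)
            g = pc_cost_gradient(v, x)
            for i in range(4):
                e = np.zeros(4)
                e[i] = h
                fd = (pc_cost(v + e, x) - pc_cost(v - e, x)) / (2 * h)
                assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_cost_zero_when_aligned(self):
        v = np.array([1.0, 0.0])
        x = np.array([3.0, 0.0])
        assert pc_cost(v, x) == pytest.approx(0.0, abs=1e-12)


class TestTrackPc:
    def test_tracks_dominant_eigenvector(self):
        rng = np.random.default_rng(0)
        X = np.linalg.cholesky(np.diag([4.0, 1.0, 0.5])) @ rng.standard_normal((3, 4000))
        X = 0.3 * X / X.std()
        res = track_pc(X, beta=0.6)
        v = res.v / np.linalg.norm(res.v)
        assert abs(v[0]) > 0.98  # dominant direction is the first axis
        assert abs(np.linalg.norm(res.v) - 1.0) < 0.1

    def test_divergence_raises(self):
        rng = np.random.default_rng(0)
        X = np.linalg.cholesky(np.diag([4.0, 1.0, 0.5])) @ rng.standard_normal((3, 4000))
        X /= X.std()
        with pytest.raises(RuntimeError, match="reduce beta"):
            track_pc(X, beta=0.6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            track_pc(np.zeros((2, 10)), beta=0.0)
        with pytest.raises(ValueError):
            track_pc(np.ones((2, 10)), v0=np.zeros(2))
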