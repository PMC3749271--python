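"""The full ANPCA cascade run in streaming (real-time) fashion.

Order of operations on a (band-passed) recording:

1. batch pre-separation (spatial whitening + delayed-covariance rotation)
   computed once on the block, giving the fixed transform ``V = V_x̃ᵀ B``;
2. per-block adaptive whitening updates of ``P`` (blocks of ~1 s);
3. per-sample nonlinear-PCA updates of ``W``;
4. per-sample LMS updates of the mixing estimate ``Q``.

A single data block (7000 samples by default) is replayed cyclically for a
number of epochs, mirroring how convergence is studied: the same
coefficients keep updating on the repeated block. When the true mixing is
known, the performance index of the combined system ``Wᵀ P V A`` is logged
every few iterations and per epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from anpca.data import Recording
from anpca.metrics import (
    NOT_CONVERGED,
    QualityReport,
    combined_system,
    convergence_epochs,
    performance_index,
    pi_db,
)
from anpca.preseparation import DEFAULT_TAUS, PreSeparationState, pre_separate
from anpca.separation import SeparationState, separation_init, separation_update
from anpca.whitening import WhiteningState, whiten_init, whiten_update

logger = logging.getLogger(__name__)

__all__ = ["ANPCAResult", "run_anpca"]


@dataclass
class ANPCAResult:
    """All states and diagnostics of one streaming run."""

    presep: PreSeparationState
    whitening: WhiteningState
    separation: SeparationState
    Q: np.ndarray
    y: np.ndarray                    # separated signals over the block (final matrices)
    report: QualityReport | None
    ortho_trace: np.ndarray
    n_iterations: int
    block_len: int

    @property
    def unmixing(self) -> np.ndarray:
        """Total sensor-to-output transform ``Wᵀ P V``."""
        return combined_system(
            self.separation.W.T, self.whitening.P, self.presep.V_total
        )


def run_anpca(
    rec: Recording,
    truth_A: np.ndarray | None = None,
    n_keep: int | str = "auto",
    tau: int | tuple[int, ...] = DEFAULT_TAUS,
    xi: float = 0.01,
    gamma: float = 0.002,
    alpha: float = 0.3,
    eta0: float = 0.1,
    mu0: float = 0.1,
    epochs: int = 10,
    block_len: int = 7000,
    whiten_block: int = 256,
    rule: str = "printed",
    nonlinearity: str = "tanh",
    ortho_every: int = 100,
    log_every: int = 50,
    conv_tol: float = 0.01,
    max_iterations: int | None = None,
) -> ANPCAResult:
    """Run the four-step cascade on a recording.

    Parameters
    ----------
    rec : Recording
        Input (already band-passed) recording.
    truth_A : array, optional
        True mixing matrix; enables performance-index logging.
    epochs : int
        Number of cyclic passes over the data block.
    block_len : int
        Samples per replayed block (the recording is cropped to this).
    max_iterations : int, optional
        Hard cap on total coefficient updates (overrides ``epochs`` when
        reached first).

    Returns
    -------
    ANPCAResult
        Final states, separated signals, and (when ground truth is given)
        a :class:`~anpca.metrics.QualityReport`.
    """
    K = min(block_len, rec.n_samples)
    X = rec.X[:, :K] - rec.X[:, :K].mean(axis=1, keepdims=True)
    block_rec = Recording(X=X, fs=rec.fs, channel_labels=rec.channel_labels)

    presep, x_pre = pre_separate(block_rec, n_keep=n_keep, tau=tau)
    n = presep.n_keep
    V = presep.V_total

    wstate = whiten_init(n, eta0=eta0, xi=xi)
    sstate = separation_init(
        n, gamma=gamma, mu0=mu0, rule=rule,
        nonlinearity=nonlinearity, ortho_every=ortho_every,
    )
    Q = np.zeros((rec.n_channels, n))

    track_pi = truth_A is not None
    pi_iter: list[tuple[int, float]] = []
    pi_epochs: list[float] = []
    ortho_trace: list[float] = []

    def current_pi() -> float:
        G = combined_system(sstate.W.T, wstate.P, V) @ truth_A
        return performance_index(G)

    it = 0
    stop = False
    for epoch in range(epochs):
        for start in range(0, K, whiten_block):
            xb = x_pre[:, start : start + whiten_block]
            whiten_update(wstate, xb)
            ub = wstate.P @ xb
            for j in range(ub.shape[1]):
                u = ub[:, j]
                separation_update(sstate, u)
                yk = sstate.W.T @ u
                e = X[:, start + j] - Q @ yk
                # estimation gain self-normalized by output power (Eq-33-style
                # time-varying rate), keeping the LMS rule unconditionally stable
                Q += (alpha / (yk @ yk + 1e-12)) * np.outer(e, yk)
                it += 1
                if it % log_every == 0:
                    ortho_trace.append(sstate.orthogonality_error())
                    if track_pi:
                        pi_iter.append((it, current_pi()))
                if max_iterations is not None and it >= max_iterations:
                    stop = True
                    break
            if stop:
                break
        if track_pi:
            pi_epochs.append(current_pi())
            logger.info("epoch %d: PI = %.4g", epoch + 1, pi_epochs[-1])
        if stop:
            break

    if not np.all(np.isfinite(Q)):
        raise RuntimeError("mixing estimation diverged; reduce alpha")

    report = None
    if track_pi:
        pi_final = pi_epochs[-1] if pi_epochs else current_pi()
        if len(pi_epochs) >= 2:
            ce = convergence_epochs(np.asarray(pi_epochs), tol=conv_tol)
        else:
            ce = NOT_CONVERGED
        report = QualityReport(
            C=combined_system(sstate.W.T, wstate.P, V),
            pi_final=pi_final,
            pi_db_final=pi_db(pi_final),
            pi_iterations=np.asarray(pi_iter) if pi_iter else np.empty((0, 2)),
            pi_epochs=np.asarray(pi_epochs),
            converged_epoch=ce,
            converged=ce != NOT_CONVERGED,
        )

    u_all = wstate.P @ x_pre
    y = sstate.W.T @ u_all
    return ANPCAResult(
        presep=presep, whitening=wstate, separation=sstate, Q=Q, y=y,
        report=report, ortho_trace=np.asarray(ortho_trace),
        n_iterations=it, block_len=K,
    )
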