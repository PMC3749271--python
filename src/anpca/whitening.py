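"""Adaptive whitening (step 2): online decorrelation with a self-adjusting gain.

The whitening matrix ``P`` is learned by stochastic gradient descent on

    J2(P) = ¼ ‖E{uuᵀ} - I_N‖²_F ,       u = P x⌣ ,

whose flow is ``dP/dt = η (I_N - R_uu) P``. In discrete time the covariance
``R̂_uu`` is re-estimated over short signal blocks and

    P(k+1) = P(k) + η(k) (I_N - R̂_uu) P(k) ,

with the gain ``η`` following the adaptive schedule of
:func:`anpca.adaptive.adaptive_rate` driven by ‖u‖² (block mean). The fixed
point is any ``P`` with ``P R_xx Pᵀ = I``; already-white input with
``P = I`` is left unchanged up to sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from anpca.adaptive import adaptive_rate
from anpca.data import DimensionError

__all__ = ["WhiteningState", "whiten_init", "whiten_update", "whiten_run", "whiteness_error"]


@dataclass
class WhiteningState:
    """Adaptive whitening matrix and its learning parameters."""

    P: np.ndarray
    eta: float
    xi: float                       # forgetting rate of the gain schedule
    R_hat: np.ndarray | None = None # last block covariance estimate
    n_updates: int = 0
    j2: float = np.inf              # last cost value ¼‖R̂ - I‖²_F

    @property
    def n(self) -> int:
        return self.P.shape[0]


def whiten_init(n: int, eta0: float = 0.1, xi: float = 0.01) -> WhiteningState:
    """Initial state: ``P = I_N`` and a modest starting gain.

    The starting gain is uncritical because the schedule self-normalizes
    by the signal power within a few updates.
    """
    if not (0 < xi < 1):
        raise ValueError("forgetting rate xi must be in (0, 1)")
    return WhiteningState(P=np.eye(n), eta=eta0, xi=xi)


def whiteness_error(R: np.ndarray) -> float:
    """Departure from whiteness, ‖R - I‖_F / N."""
    n = R.shape[0]
    return float(np.linalg.norm(R - np.eye(n)) / n)


def whiten_update(state: WhiteningState, block: np.ndarray) -> WhiteningState:
    """One adaptive update of ``P`` from a signal block (channels x samples).

    Mutates and returns ``state``. Raises ``RuntimeError`` on numerical
    blow-up.
    """
    block = np.atleast_2d(block)
    if block.shape[0] != state.n:
        raise DimensionError(
            f"block has {block.shape[0]} channels, whitener expects {state.n}"
        )
    u = state.P @ block
    k = block.shape[1]
    R = (u @ u.T) / k
    normsq = float(np.mean(np.sum(u * u, axis=0)))
    state.eta = adaptive_rate(state.eta, normsq, state.xi)
    I = np.eye(state.n)
    state.P = state.P + state.eta * (I - R) @ state.P
    if not np.all(np.isfinite(state.P)):
        raise RuntimeError(
            f"whitening diverged after {state.n_updates + 1} updates; "
            "reduce eta0 or check input scaling"
        )
    state.R_hat = R
    state.j2 = 0.25 * float(np.linalg.norm(R - I) ** 2)
    state.n_updates += 1
    return state


@dataclass
class WhitenRunResult:
    P: np.ndarray
    u: np.ndarray
    converged: bool
    j2_trajectory: np.ndarray = field(default_factory=lambda: np.empty(0))
    state: WhiteningState | None = None


def whiten_run(
    x: np.ndarray,
    xi: float = 0.01,
    eta0: float = 0.1,
    block: int = 256,
    max_epochs: int = 100,
    tol: float = 0.05,
) -> WhitenRunResult:
    """Iterate block updates over the signal until whiteness is reached.

    Convergence is checked once per epoch (full pass) on the whole-signal
    covariance of ``u = P x``: ``‖R_uu - I‖_F / N < tol``. If the budget is
    exhausted the best state is returned with ``converged=False``.
    """
    x = np.atleast_2d(np.asarray(x, float))
    n, K = x.shape
    state = whiten_init(n, eta0=eta0, xi=xi)
    j2_epochs = []
    converged = False
    for _ in range(max_epochs):
        for start in range(0, K, block):
            whiten_update(state, x[:, start : start + block])
        u = state.P @ x
        R = (u @ u.T) / K
        j2_epochs.append(0.25 * float(np.linalg.norm(R - np.eye(n)) ** 2))
        if whiteness_error(R) < tol:
            converged = True
            break
    u = state.P @ x
    return WhitenRunResult(
        P=state.P, u=u, converged=converged,
        j2_trajectory=np.asarray(j2_epochs), state=state,
    )
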