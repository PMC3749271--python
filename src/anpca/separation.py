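"""Nonlinear PCA separation (step 3): rotating whitened signals to sources.

With whitened input ``u`` the residual mixing is orthogonal, and the
nonlinear PCA learning rule finds it by driving the nonlinear covariance
``E{f(y)(u - f(y))ᵀ}`` toward diagonal balance, where ``y = Wᵀu`` and
``f(t) = tanh(t)`` (the associated even potential is ``g(t) = ln cosh t``).
Higher-order statistics enter through the nonlinearity, so Gaussian-only
source sets are not identifiable -- the rule then wanders without
converging to anything meaningful, which is the expected behaviour of any
blind separation contrast.

Two update rules are available:

* ``rule="printed"`` (default):
  ``W(k+1) = W(k) + μ(k) · f(y)·(uᵀ - f(y)ᵀ) · W(k)``,
  combined with periodic symmetric orthonormalization that enforces the
  orthogonality assumption ``WᵀW = I`` underlying its derivation.
* ``rule="standard_npca"``: the classical subspace rule
  ``W(k+1) = W(k) + μ(k) · (u - W f(y)) f(y)ᵀ``.

The gain ``μ`` follows the adaptive schedule of
:func:`anpca.adaptive.adaptive_rate` driven by ‖y‖², with forgetting rate
``γ`` (0.002 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from anpca.adaptive import adaptive_rate, symmetric_orthonormalize
from anpca.data import DimensionError

__all__ = ["SeparationState", "separation_init", "separation_update", "separate"]

_NONLINEARITIES = {
    "tanh": np.tanh,
    "cubic": lambda y: y**3,
}


@dataclass
class SeparationState:
    """Separation matrix ``W`` and its adaptive learning parameters."""

    W: np.ndarray
    mu: float
    gamma: float
    rule: str = "printed"
    nonlinearity: str = "tanh"
    ortho_every: int = 100
    n_updates: int = 0

    def __post_init__(self) -> None:
        if self.rule not in ("printed", "standard_npca"):
            raise ValueError(f"unknown separation rule {self.rule!r}")
        if self.nonlinearity not in _NONLINEARITIES:
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")

    @property
    def f(self):
        return _NONLINEARITIES[self.nonlinearity]

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def orthogonality_error(self) -> float:
        """‖WᵀW - I‖_F / N, the soft-orthogonality residual."""
        n = self.n
        return float(np.linalg.norm(self.W.T @ self.W - np.eye(n)) / n)


def separation_init(
    n: int,
    gamma: float = 0.002,
    mu0: float = 0.1,
    rule: str = "printed",
    nonlinearity: str = "tanh",
    ortho_every: int = 100,
) -> SeparationState:
    """Initial state with ``W(0) = I``."""
    if not (0 < gamma < 1):
        raise ValueError("forgetting rate gamma must be in (0, 1)")
    return SeparationState(
        W=np.eye(n), mu=mu0, gamma=gamma, rule=rule,
        nonlinearity=nonlinearity, ortho_every=ortho_every,
    )


def separation_update(state: SeparationState, u: np.ndarray) -> SeparationState:
    """One per-sample update. Mutates and returns ``state``.

    Raises ``RuntimeError`` with a diagnostic on numerical blow-up (the
    ``standard_npca`` rule is the suggested fallback when the printed rule
    destabilizes).
    """
    u = np.asarray(u, float)
    if u.shape != (state.n,):
        raise DimensionError(f"sample has shape {u.shape}, expected ({state.n},)")
    W = state.W
    y = W.T @ u
    fy = state.f(y)
    state.mu = adaptive_rate(state.mu, float(y @ y), state.gamma)
    if state.rule == "printed":
        W = W + state.mu * np.outer(fy, u - fy) @ W
    else:  # standard_npca
        W = W + state.mu * np.outer(u - W @ fy, fy)
    if not np.all(np.isfinite(W)):
        raise RuntimeError(
            f"separation diverged at update {state.n_updates + 1} "
            f"(rule={state.rule!r}); try rule='standard_npca' or a larger gamma"
        )
    state.n_updates += 1
    if state.ortho_every and state.n_updates % state.ortho_every == 0:
        W = symmetric_orthonormalize(W)
    state.W = W
    return state


@dataclass
class SeparateResult:
    W: np.ndarray
    y: np.ndarray
    orthogonality_trace: np.ndarray
    state: SeparationState


def separate(
    u: np.ndarray,
    gamma: float = 0.002,
    passes: int = 1,
    mu0: float = 0.1,
    rule: str = "printed",
    nonlinearity: str = "tanh",
    ortho_every: int = 100,
    trace_every: int = 50,
) -> SeparateResult:
    """Stream a whitened signal through the NPCA rule ``passes`` times.

    Returns the final ``W``, the separated signals ``y = Wᵀu`` computed
    with the final matrix, and the ‖WᵀW - I‖ trace sampled every
    ``trace_every`` updates.
    """
    u = np.atleast_2d(np.asarray(u, float))
    n, K = u.shape
    state = separation_init(
        n, gamma=gamma, mu0=mu0, rule=rule,
        nonlinearity=nonlinearity, ortho_every=ortho_every,
    )
    trace = []
    for _ in range(passes):
        for k in range(K):
            separation_update(state, u[:, k])
            if state.n_updates % trace_every == 0:
                trace.append(state.orthogonality_error())
    return SeparateResult(
        W=state.W, y=state.W.T @ u,
        orthogonality_trace=np.asarray(trace), state=state,
    )
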