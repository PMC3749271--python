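"""Shared pieces of the adaptive learning stages.

The whitening, separation, and estimation steps all use a self-adjusting
gain of the recursive-least-squares family,

    1/rate(k) = (1 - forget) * 1/rate(k-1) + ||z(k)||^2 ,

where ``z`` is the stage's output vector and ``forget`` in (0, 1) is the
forgetting rate: the fraction of the accumulated inverse gain discarded per
update, so the effective memory is about ``1/forget`` updates. Early on the
gain anneals like 1/k; it then plateaus at ``forget / E||z||^2``. A rate of
``forget=1`` makes the gain memoryless (``rate = 1/||z||^2``, normalized
LMS).
"""

from __future__ import annotations

import numpy as np

__all__ = ["adaptive_rate", "symmetric_orthonormalize"]


def adaptive_rate(prev_rate: float, normsq: float, forget: float) -> float:
    """One step of the self-adjusting learning-rate recursion."""
    if prev_rate <= 0:
        raise ValueError("learning rate must stay positive")
    if not (0 < forget <= 1):
        raise ValueError("forgetting rate must be in (0, 1]")
    return 1.0 / ((1.0 - forget) / prev_rate + normsq)


def symmetric_orthonormalize(W: np.ndarray) -> np.ndarray:
    """Project ``W`` to the nearest orthogonal matrix: ``W (WᵀW)^(-1/2)``."""
    lam, V = np.linalg.eigh(W.T @ W)
    if np.any(lam <= 0):
        raise np.linalg.LinAlgError("matrix is rank deficient; cannot orthonormalize")
    return W @ (V / np.sqrt(lam)) @ V.T
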