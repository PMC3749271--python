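"""Mixing estimation, separation quality metrics, and target classification.

The quality of a blind separation is judged on the combined system -- the
product of every learned transform applied to the true mixing. Perfect
separation leaves a scaled permutation matrix (each output carries exactly
one source); the performance index quantifies the deviation from that
ideal on a 0..1 scale and is conventionally reported in decibels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from anpca.data import DimensionError, EpochSet, EventSequence, N_STIMULI

__all__ = [
    "EstimationState",
    "estimate_mixing",
    "combined_system",
    "performance_index",
    "pi_db",
    "pi_from_db",
    "convergence_epochs",
    "NOT_CONVERGED",
    "ClassificationResult",
    "classify_blocks",
    "QualityReport",
]


# ---------------------------------------------------------------------------
# Mixing-matrix estimation (step 4)
# ---------------------------------------------------------------------------

@dataclass
class EstimationState:
    """LMS estimate ``Q`` of the mixing matrix, fit by ``x̂ = Q y``."""

    Q: np.ndarray
    alpha: float
    n_updates: int = 0
    residual_trace: list[float] = field(default_factory=list)


def estimate_mixing(
    y: np.ndarray,
    x_target: np.ndarray,
    alpha: float = 0.3,
    epochs: int = 1,
) -> EstimationState:
    """Estimate the mixing matrix by a stochastic (LMS) reconstruction rule.

    Per sample: ``Q ← Q + α(k) (x̂ - Q y) yᵀ`` with ``Q(0) = 0`` and the
    time-varying gain ``α(k) = α / ‖y(k)‖²`` -- the estimation gain is
    self-normalized by the output power like the gains of the whitening
    and separation steps, which keeps the stochastic rule stable for any
    signal scale (plain LMS is only stable while ``α‖y‖² < 2``). The
    columns of the converged ``Q`` estimate the mixing columns up to the
    usual permutation/scale indeterminacy of ``y``.
    """
    y = np.atleast_2d(np.asarray(y, float))
    x_target = np.atleast_2d(np.asarray(x_target, float))
    if y.shape[1] != x_target.shape[1]:
        raise DimensionError("y and x_target must be sample-aligned")
    n, K = y.shape
    m = x_target.shape[0]
    state = EstimationState(Q=np.zeros((m, n)), alpha=alpha)
    for _ in range(epochs):
        sq = 0.0
        for k in range(K):
            yk = y[:, k]
            e = x_target[:, k] - state.Q @ yk
            state.Q += (alpha / (yk @ yk + 1e-12)) * np.outer(e, yk)
            if not np.all(np.isfinite(state.Q)):
                raise RuntimeError(
                    f"mixing estimation diverged at update {state.n_updates} "
                    f"(alpha={alpha}); reduce alpha"
                )
            sq += float(e @ e)
            state.n_updates += 1
        state.residual_trace.append(np.sqrt(sq / K))
    return state


# ---------------------------------------------------------------------------
# Combined system and performance index
# ---------------------------------------------------------------------------

def combined_system(W: np.ndarray, P: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Combined transform ``C = W · P · V``.

    ``V`` is the total pre-separation map (rotation times spatial
    whitener), ``P`` the adaptive whitener, and ``W`` the separation
    matrix *in its unmixing orientation* (i.e. pass ``Wᵀ`` of a state whose
    outputs are ``y = Wᵀu``).
    """
    W, P, V = (np.atleast_2d(np.asarray(a, float)) for a in (W, P, V))
    if W.shape[1] != P.shape[0] or P.shape[1] != V.shape[0]:
        raise DimensionError(
            f"non-conformable shapes {W.shape} x {P.shape} x {V.shape}"
        )
    return W @ P @ V


def performance_index(C: np.ndarray) -> float:
    """Separation performance index of a (square) combined matrix.

    With ``Ca_i = max_j |c_ij|² / Σ_j |c_ij|²`` (row sharpness) and
    ``Cb_i = max_j |c_ji|² / Σ_j |c_ji|²`` (column sharpness),

        PI = 1/(2(M-1)) · Σ_i [(1 - Ca_i) + (1 - Cb_i)] .

    PI is 0 exactly when ``C`` is a scaled permutation (each source appears
    in exactly one output) and 1 for a maximally mixed (all-equal) square
    matrix; it is invariant to row/column permutation and global scaling.
    The index is evaluated in exact rational arithmetic so that both
    boundary values are attained bit-exactly (matrices are small, so the
    cost is negligible).
    """
    C = np.atleast_2d(np.asarray(C))
    M, Nc = C.shape
    if M != Nc:
        raise DimensionError(f"combined system must be square, got {C.shape}")
    if M < 2:
        raise DimensionError("performance index needs at least a 2x2 system")

    def sq(c) -> Fraction:
        z = complex(c)
        return Fraction(z.real) ** 2 + Fraction(z.imag) ** 2

    A2 = [[sq(C[i, j]) for j in range(M)] for i in range(M)]
    total = Fraction(0)
    for i in range(M):
        row = A2[i]
        col = [A2[j][i] for j in range(M)]
        rs, cs = sum(row), sum(col)
        if rs == 0 or cs == 0:
            raise ValueError("all-zero row or column: performance index undefined")
        total += (rs - max(row)) / rs + (cs - max(col)) / cs
    return float(total / (2 * (M - 1)))


def pi_db(pi: float) -> float:
    """Performance index in decibels, ``20 log10(PI)`` (0 maps to -inf)."""
    if pi < 0:
        raise ValueError("performance index cannot be negative")
    if pi == 0:
        return -np.inf
    return 20.0 * np.log10(pi)


def pi_from_db(db: float) -> float:
    """Inverse of :func:`pi_db`."""
    return 10.0 ** (db / 20.0)


NOT_CONVERGED = -1


def convergence_epochs(pi_trajectory: np.ndarray, tol: float = 0.01) -> int:
    """First epoch from which the PI trajectory has settled.

    Returns the smallest 1-based epoch ``e`` whose two following
    epoch-to-epoch relative changes ``|PI(e') - PI(e'-1)| / PI(e'-1)`` are
    both below ``tol`` (one suffices at the trajectory tail); a perfectly
    flat trajectory converges at epoch 1. Returns ``NOT_CONVERGED`` if the
    criterion is never met.
    """
    pi = np.asarray(pi_trajectory, float)
    if pi.size < 2:
        raise ValueError("trajectory needs at least 2 epochs")
    rel = np.abs(np.diff(pi)) / pi[:-1]
    small = rel < tol
    for e in range(small.size):
        window = small[e : e + 2]
        if window.all():
            return e + 1
    return NOT_CONVERGED


# ---------------------------------------------------------------------------
# Block-wise target classification
# ---------------------------------------------------------------------------

@dataclass
class ClassificationResult:
    """Per-block target predictions on the separated ERP component."""

    predictions: np.ndarray          # predicted stimulus id per block (at m=avg_blocks)
    target_id: int
    accuracy: float
    avg_blocks: int
    accuracy_by_m: dict[int, float]  # accuracy as a function of the averaging depth


def classify_blocks(
    epochs: EpochSet,
    events: EventSequence,
    score_window: tuple[float, float] = (0.25, 0.45),
    avg_blocks: int = 3,
    channel: int = 0,
    max_m: int | None = None,
) -> ClassificationResult:
    """Predict the attended stimulus per block from P300-window amplitude.

    Scoring: for each block and stimulus id, the mean amplitude of its
    epoch on the chosen channel within ``score_window`` (relative to
    onset), averaged over the current and up to ``m - 1`` preceding blocks
    of the same stimulus; the predicted target is the argmax. Accuracy is
    the fraction of blocks predicted correctly, reported for every
    averaging depth ``m`` up to ``max_m``.
    """
    blocks = np.unique(events.block_ids)
    if blocks.size < 1:
        raise ValueError("need at least one stimulus block to classify")
    t = epochs.times
    sel = (t >= score_window[0]) & (t <= score_window[1])
    if not sel.any():
        raise ValueError("score window outside the epoch window")
    # per-event scalar score
    scores = epochs.data[:, channel, sel].mean(axis=1)

    # score[block, stimulus]
    n_b = blocks.size
    table = np.full((n_b, N_STIMULI), np.nan)
    for bi, b in enumerate(blocks):
        m_evt = events.block_ids == b
        table[bi, events.stimulus_ids[m_evt] - 1] = scores[m_evt]

    max_m = max_m or n_b
    accuracy_by_m: dict[int, float] = {}
    preds_at_default = None
    for m in range(1, max_m + 1):
        preds = np.empty(n_b, dtype=int)
        for bi in range(n_b):
            lo = max(0, bi - m + 1)
            preds[bi] = int(np.argmax(table[lo : bi + 1].mean(axis=0))) + 1
        accuracy_by_m[m] = float(np.mean(preds == events.target_id))
        if m == min(avg_blocks, max_m):
            preds_at_default = preds
    return ClassificationResult(
        predictions=preds_at_default,
        target_id=events.target_id,
        accuracy=accuracy_by_m[min(avg_blocks, max_m)],
        avg_blocks=avg_blocks,
        accuracy_by_m=accuracy_by_m,
    )


# ---------------------------------------------------------------------------
# Quality report
# ---------------------------------------------------------------------------

@dataclass
class QualityReport:
    """Summary of a separation run against ground truth."""

    C: np.ndarray                    # combined unmixing transform W·P·V
    pi_final: float
    pi_db_final: float
    pi_iterations: np.ndarray        # (iteration, PI) pairs
    pi_epochs: np.ndarray            # PI at the end of each epoch
    converged_epoch: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "pi_final": self.pi_final,
            "pi_db_final": None if np.isinf(self.pi_db_final) else self.pi_db_final,
            "converged_epoch": self.converged_epoch,
            "converged": self.converged,
            "pi_epochs": [float(p) for p in self.pi_epochs],
            "pi_iterations": [[int(i), float(p)] for i, p in self.pi_iterations],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def first_iteration_below(self, threshold: float) -> int:
        """First logged iteration with PI < threshold (-1 if never)."""
        for it, p in self.pi_iterations:
            if p < threshold:
                return int(it)
        return -1
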