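"""Reference separation algorithms for performance-index comparisons.

Implemented: SOBI (second-order blind identification -- exact whitening
followed by approximate joint diagonalization of lagged covariances by
Jacobi rotations) and plain NPCA (the nonlinear-PCA separation rule alone
on exactly whitened data, without the pre-separation stage). Further
algorithms can be plugged into :data:`BASELINE_REGISTRY` without touching
core code.

All baselines are scored with the same permutation/scale-invariant
performance index. ``iterations`` means samples processed by coefficient
updates; for the batch SOBI sweeps this is sweeps x block length (one
sweep revisits every sample), with the sweep count reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from anpca.data import Recording
from anpca.metrics import performance_index
from anpca.separation import separation_init, separation_update

__all__ = ["BaselineResult", "sobi", "plain_npca", "compare", "BASELINE_REGISTRY"]


@dataclass
class BaselineResult:
    algorithm: str
    W_equiv: np.ndarray                  # total unmixing transform (outputs = W_equiv @ x)
    pi_curve: np.ndarray                 # (iteration, PI) pairs; empty without truth
    iterations_to_threshold: dict[float, int] = field(default_factory=dict)
    sweeps: int | None = None            # Jacobi sweeps (SOBI only)
    warning: str | None = None

    def first_below(self, threshold: float) -> int:
        for it, p in self.pi_curve:
            if p < threshold:
                return int(it)
        return -1


def _exact_whitener(
    X: np.ndarray, rel_floor: float = 1e-9
) -> tuple[np.ndarray, np.ndarray]:
    """Batch whitening transform from the sample covariance.

    Eigenvalues below ``rel_floor`` times the largest are treated as
    numerically zero and their directions dropped (noiseless mixtures of
    fewer sources than channels are rank deficient by construction).
    """
    K = X.shape[1]
    R = (X @ X.T) / K
    lam, V = np.linalg.eigh(R)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    if lam[0] <= 0:
        raise ValueError("singular covariance; cannot whiten")
    keep = lam > rel_floor * lam[0]
    Wh = (V[:, keep] / np.sqrt(lam[keep])).T
    return Wh, Wh @ X


def _lagged_covariances(Z: np.ndarray, lags: tuple[int, ...]) -> list[np.ndarray]:
    K = Z.shape[1]
    mats = []
    for t in lags:
        R = (Z[:, t:] @ Z[:, :-t].T) / (K - t)
        mats.append(0.5 * (R + R.T))
    return mats


def _joint_diag_sweep(mats: list[np.ndarray], U: np.ndarray, threshold: float) -> bool:
    """One Jacobi sweep over all index pairs; rotates mats and U in place.

    Returns True when any rotation exceeded the angle threshold.
    """
    n = U.shape[0]
    rotated = False
    for p in range(n - 1):
        for q in range(p + 1, n):
            ton = sum(m[p, p] - m[q, q] for m in mats)
            toff = sum(m[p, q] + m[q, p] for m in mats)
            theta = 0.5 * np.arctan2(toff, ton + np.hypot(ton, toff))
            c, s = np.cos(theta), np.sin(theta)
            if abs(s) > threshold:
                rotated = True
                for m in mats:
                    rp, rq = m[p, :].copy(), m[q, :].copy()
                    m[p, :], m[q, :] = c * rp + s * rq, -s * rp + c * rq
                    cp, cq = m[:, p].copy(), m[:, q].copy()
                    m[:, p], m[:, q] = c * cp + s * cq, -s * cp + c * cq
                up, uq = U[p, :].copy(), U[q, :].copy()
                U[p, :], U[q, :] = c * up + s * uq, -s * up + c * uq
    return rotated


def sobi(
    rec: Recording,
    lags: tuple[int, ...] = tuple(range(1, 11)),
    truth_A: np.ndarray | None = None,
    max_sweeps: int = 100,
    threshold: float = 1e-8,
    degeneracy_tol: float = 0.02,
) -> BaselineResult:
    """Second-order blind identification.

    Whitens the data exactly, then jointly diagonalizes the symmetrized
    lagged covariances with Jacobi rotations. With a single lag whose
    source autocorrelations coincide, the rotation is not identifiable and
    a warning is attached to the result.
    """
    if len(lags) < 1:
        raise ValueError("need at least one lag")
    X = rec.X - rec.X.mean(axis=1, keepdims=True)
    Wh, Z = _exact_whitener(X)
    mats = _lagged_covariances(Z, tuple(lags))
    n = Z.shape[0]
    U = np.eye(n)

    warning = None
    if len(lags) == 1:
        d = np.sort(np.diag(mats[0]))
        if n > 1 and np.min(np.diff(d)) < degeneracy_tol:
            warning = (
                "near-equal lagged autocorrelations: single-lag SOBI rotation "
                "is not identifiable"
            )

    K = rec.n_samples
    pi_curve = []
    sweeps = 0
    if truth_A is not None:
        pi_curve.append((0, performance_index(U @ Wh @ truth_A)))
    for sweep in range(1, max_sweeps + 1):
        rotated = _joint_diag_sweep(mats, U, threshold)
        sweeps = sweep
        if truth_A is not None:
            pi_curve.append((sweep * K, performance_index(U @ Wh @ truth_A)))
        if not rotated:
            break
    res = BaselineResult(
        algorithm="sobi",
        W_equiv=U @ Wh,
        pi_curve=np.asarray(pi_curve) if pi_curve else np.empty((0, 2)),
        sweeps=sweeps,
        warning=warning,
    )
    for thr in (0.1, 0.05):
        res.iterations_to_threshold[thr] = res.first_below(thr)
    return res


def plain_npca(
    rec: Recording,
    gamma: float = 0.002,
    passes: int = 1,
    truth_A: np.ndarray | None = None,
    rule: str = "printed",
    ortho_every: int = 100,
    log_every: int = 50,
    mu0: float = 0.1,
) -> BaselineResult:
    """NPCA separation rule alone, on exactly (batch) whitened data.

    No pre-separation stage: the rule starts from the whitened mixture
    with ``W(0) = I`` and must find the full residual rotation itself.
    """
    X = rec.X - rec.X.mean(axis=1, keepdims=True)
    Wh, U_sig = _exact_whitener(X)
    n, K = U_sig.shape
    state = separation_init(n, gamma=gamma, mu0=mu0, rule=rule, ortho_every=ortho_every)
    pi_curve = []
    it = 0
    for _ in range(passes):
        for k in range(K):
            separation_update(state, U_sig[:, k])
            it += 1
            if truth_A is not None and it % log_every == 0:
                pi_curve.append((it, performance_index(state.W.T @ Wh @ truth_A)))
    res = BaselineResult(
        algorithm="plain_npca",
        W_equiv=state.W.T @ Wh,
        pi_curve=np.asarray(pi_curve) if pi_curve else np.empty((0, 2)),
    )
    for thr in (0.1, 0.05):
        res.iterations_to_threshold[thr] = res.first_below(thr)
    return res


BASELINE_REGISTRY: dict[str, Callable[..., BaselineResult]] = {
    "sobi": sobi,
    "plain_npca": plain_npca,
}


def compare(
    algorithms: tuple[str, ...] = ("anpca", "sobi", "plain_npca"),
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4, 5),
    thresholds: tuple[float, ...] = (0.1, 0.05),
    block_len: int = 7000,
    epochs: int = 1,
    **session_kwargs,
) -> pd.DataFrame:
    """Run several algorithms on identical synthetic sessions.

    For each seed one synthetic oddball mixture is generated, band-passed,
    and fed to every requested algorithm; the table reports the final PI
    and the iterations (samples processed) needed to reach each PI
    threshold (-1 when never reached).
    """
    from anpca.experiments import make_session  # deferred: avoids cycle
    from anpca.pipeline import run_anpca

    rows = []
    for seed in seeds:
        sess = make_session(seed, block_len=block_len, **session_kwargs)
        filtered, truth_A = sess.rec, sess.A_eff
        for algo in algorithms:
            if algo == "anpca":
                r = run_anpca(
                    filtered, truth_A=truth_A, n_keep=sess.model.n_sources,
                    epochs=epochs, block_len=block_len,
                )
                curve = r.report.pi_iterations
                row = {
                    "algorithm": "anpca",
                    "seed": seed,
                    "final_pi": r.report.pi_final,
                    "sweeps": None,
                }
                for thr in thresholds:
                    row[f"iters_below_{thr}"] = r.report.first_iteration_below(thr)
            elif algo in BASELINE_REGISTRY:
                res = BASELINE_REGISTRY[algo](filtered, truth_A=truth_A)
                curve = res.pi_curve
                row = {
                    "algorithm": algo,
                    "seed": seed,
                    "final_pi": float(curve[-1, 1]) if len(curve) else np.nan,
                    "sweeps": res.sweeps,
                }
                for thr in thresholds:
                    row[f"iters_below_{thr}"] = res.first_below(thr)
            else:
                raise ValueError(f"unknown algorithm {algo!r}")
            row["n_logged"] = len(curve)
            rows.append(row)
    return pd.DataFrame(rows)
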