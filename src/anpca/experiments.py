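"""Canned simulation experiments shared by tests, the CLI, and scripts.

The reference study conditions: eight channels at 256 Hz, four sources
(one P300-like ERP, two rhythmic backgrounds, one slow artifact), a
well-conditioned mixing (condition number <= 10), no sensor noise, 350 ms
ISI, and a single replayed block of 7000 samples with the published
learning parameters (xi = 0.01, gamma = 0.002, alpha = 0.3, W(0) = I).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from anpca.data import MixtureModel, Recording
from anpca.metrics import NOT_CONVERGED
from anpca.pipeline import ANPCAResult, run_anpca
from anpca.preprocess import FilterSpec, bandpass
from anpca.synth import simulate_session

__all__ = ["Session", "make_session", "RunSummary", "convergence_experiment"]

BLOCK_LEN = 7000


@dataclass
class Session:
    """One band-passed synthetic session with its ground truth.

    ``A_eff`` is the mixing with each column scaled by the std of the
    corresponding band-passed source over the block; it is the mixing of
    the *unit-variance* sources the separation model assumes (R_ss = I),
    and therefore the matrix the performance index is scored against.
    """

    rec: Recording                  # filtered, cropped to the block
    model: MixtureModel
    A_eff: np.ndarray
    sources_filtered: np.ndarray    # band-passed, cropped source rows
    events: object

    @property
    def A(self) -> np.ndarray:
        return self.model.A


def make_session(
    seed: int,
    block_len: int = BLOCK_LEN,
    fs: float = 256.0,
    n_channels: int = 8,
    noise_sigma: float = 0.0,
    isi: float = 0.350,
    **session_kwargs,
) -> Session:
    """Generate and band-pass one synthetic session covering a data block."""
    # enough oddball blocks to cover block_len samples
    n_blocks = int(np.ceil((block_len / fs + 1.0) / (7 * isi))) + 1
    rec, sources, model, events = simulate_session(
        n_blocks=n_blocks, isi=isi, fs=fs, n_channels=n_channels,
        noise_sigma=noise_sigma, seed=seed, **session_kwargs,
    )
    spec = FilterSpec()
    filtered = bandpass(rec, spec)
    filtered = Recording(
        X=filtered.X[:, :block_len], fs=fs, channel_labels=filtered.channel_labels
    )
    sf = bandpass(Recording(X=sources.S, fs=fs), spec).X[:, :block_len]
    sf = sf - sf.mean(axis=1, keepdims=True)
    A_eff = model.A * sf.std(axis=1)[None, :]
    return Session(rec=filtered, model=model, A_eff=A_eff,
                   sources_filtered=sf, events=events)


@dataclass
class RunSummary:
    """Headline numbers of one seeded convergence run."""

    seed: int
    pi_final: float
    pi_db_final: float
    pi_at_5000: float
    first_below_0p1: int          # iteration index; -1 if never
    converged_epoch: int
    pi_epochs: np.ndarray
    result: ANPCAResult | None = None


def _pi_at_iteration(result: ANPCAResult, iteration: int) -> float:
    curve = result.report.pi_iterations
    idx = np.searchsorted(curve[:, 0], iteration, side="right") - 1
    return float(curve[max(idx, 0), 1])


def convergence_experiment(
    seeds=(0, 1, 2, 3, 4, 5),
    epochs: int = 10,
    block_len: int = BLOCK_LEN,
    log_every: int = 50,
    keep_results: bool = False,
    **kwargs,
) -> list[RunSummary]:
    """Replayed-block convergence study over several seeded sessions.

    For each seed: generate a noiseless synthetic mixture, run the full
    cascade for ``epochs`` passes over the block while logging the
    performance index every ``log_every`` iterations, and summarize the
    final PI (linear and dB), the PI after 5000 iterations, the first
    iteration below PI = 0.1, and the convergence epoch (1% sustained
    criterion).
    """
    out = []
    for seed in seeds:
        sess = make_session(int(seed), block_len=block_len)
        res = run_anpca(
            sess.rec, truth_A=sess.A_eff, n_keep=sess.model.n_sources,
            epochs=epochs, block_len=block_len, log_every=log_every, **kwargs,
        )
        rep = res.report
        out.append(
            RunSummary(
                seed=int(seed),
                pi_final=rep.pi_final,
                pi_db_final=rep.pi_db_final,
                pi_at_5000=_pi_at_iteration(res, 5000),
                first_below_0p1=rep.first_iteration_below(0.1),
                converged_epoch=rep.converged_epoch,
                pi_epochs=rep.pi_epochs,
                result=res if keep_results else None,
            )
        )
    return out


def summarize(runs: list[RunSummary]) -> dict:
    """Aggregate statistics used in reports."""
    finals = np.array([r.pi_final for r in runs])
    at5000 = np.array([r.pi_at_5000 for r in runs])
    knees = np.array([r.first_below_0p1 for r in runs])
    epochs = np.array([r.converged_epoch for r in runs])
    return {
        "median_final_pi": float(np.median(finals)),
        "worst_final_pi_db": float(20 * np.log10(finals.max())),
        "median_pi_at_5000": float(np.median(at5000)),
        "median_first_below_0p1": float(np.median(knees)),
        "max_converged_epoch": int(epochs.max()),
        "any_not_converged": bool(np.any(epochs == NOT_CONVERGED)),
    }
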