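"""Synthetic oddball-ERP session generator.

Emulates the statistical structure of an eight-channel, 256 Hz oddball
recording: a seven-stimulus flash schedule, a small P300-like source locked
to target onsets, high-amplitude rhythmic background activity, a slow
artifact drift, a full-rank linear mixing, and additive white Gaussian
sensor noise.

Amplitude anchors: the P300 source peaks at ~1.5 µV roughly 300 ms after a
target flash, while raw background activity spans on the order of 300 µV
peak-to-peak (dropping to tens of µV after 1-12 Hz band-pass filtering).

All randomness flows through an explicit integer seed per call; repeated
calls with the same arguments are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from anpca.data import (
    N_STIMULI,
    ConfigurationError,
    DimensionError,
    EventSequence,
    MixtureModel,
    Recording,
    SourceSet,
)

__all__ = [
    "SourceParams",
    "generate_stimulus_sequence",
    "generate_sources",
    "make_mixing",
    "mix",
    "simulate_session",
]


@dataclass
class SourceParams:
    """Tunable amplitudes and shapes of the generated sources.

    The P300 template is a Gaussian bump (peak latency 300 ms, sd 60 ms);
    non-target stimuli evoke a smaller, earlier bump so that target /
    non-target discrimination is nontrivial. Background sources are AR(2)
    processes with rhythmic resonances (alpha- and theta-like) plus 1/f
    drift; the optional artifact source is a slow piecewise-linear ramp.
    """

    p300_uv: float = 1.5          # peak amplitude of the target response, µV
    p300_latency: float = 0.300   # s after stimulus onset
    p300_sd: float = 0.060        # Gaussian template width, s
    nontarget_ratio: float = 0.3  # non-target early response, fraction of p300_uv
    nontarget_latency: float = 0.150
    nontarget_sd: float = 0.040
    background_uv: float = 40.0   # RMS of each raw background source, µV
    n_background: int = 2
    background_freqs: tuple[float, ...] = (10.0, 6.0)   # AR(2) resonances, Hz
    background_radii: tuple[float, ...] = (0.98, 0.95)  # AR(2) pole radii
    drift_fraction: float = 0.3   # 1/f drift share of background RMS
    include_artifact: bool = True
    artifact_uv: float = 100.0    # RMS of the slow ramp source, µV
    artifact_breakpoint_s: float = 2.0  # mean spacing of ramp slope changes


def generate_stimulus_sequence(
    n_blocks: int,
    isi: float = 0.350,
    flash_duration: float = 0.050,
    seed: int = 0,
    start: float = 1.0,
) -> EventSequence:
    """Build a seven-stimulus oddball schedule.

    Each block flashes the seven stimuli once in a seeded random order; one
    target id is drawn once per session and kept constant across blocks.
    Onsets are evenly spaced by ``isi`` (flash + 300 ms blank), starting at
    ``start`` seconds.
    """
    if not (0.3 <= isi <= 0.5):
        raise ConfigurationError(f"isi {isi} outside the supported [0.3, 0.5] s range")
    if abs(flash_duration + 0.300 - isi) > 1e-3:
        raise ConfigurationError(
            f"flash_duration {flash_duration} + 0.300 s must equal isi {isi}"
        )
    if n_blocks < 0:
        raise ConfigurationError("n_blocks must be >= 0")

    rng = np.random.default_rng(seed)
    target = int(rng.integers(1, N_STIMULI + 1))
    stimulus_ids = np.concatenate(
        [rng.permutation(N_STIMULI) + 1 for _ in range(n_blocks)]
    ) if n_blocks else np.empty(0, dtype=int)
    n_events = N_STIMULI * n_blocks
    onsets = start + isi * np.arange(n_events)
    block_ids = np.repeat(np.arange(n_blocks), N_STIMULI)
    return EventSequence(
        onsets=onsets,
        stimulus_ids=stimulus_ids,
        block_ids=block_ids,
        target_id=target,
        flash_duration=flash_duration,
        isi=isi,
    )


def _gaussian_bump_train(
    t: np.ndarray, onsets: np.ndarray, latency: float, sd: float, amp: float
) -> np.ndarray:
    out = np.zeros_like(t)
    for onset in onsets:
        peak = onset + latency
        lo = np.searchsorted(t, peak - 5 * sd)
        hi = np.searchsorted(t, peak + 5 * sd)
        out[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - peak) / sd) ** 2)
    return out


def _background(
    n: int, fs: float, f0: float, radius: float, drift_fraction: float,
    rms: float, rng: np.random.Generator,
) -> np.ndarray:
    """AR(2) resonance driven by uniform innovations, plus slow 1/f drift."""
    a1 = 2.0 * radius * np.cos(2.0 * np.pi * f0 / fs)
    a2 = -(radius ** 2)
    # uniform innovations keep the marginal light-tailed
    innov = rng.uniform(-1.0, 1.0, size=n + 2000)
    rhythmic = signal.lfilter([1.0], [1.0, -a1, -a2], innov)[2000:]
    rhythmic /= np.std(rhythmic)

    sos = signal.butter(2, 0.7, btype="lowpass", fs=fs, output="sos")
    drift = signal.sosfilt(sos, rng.standard_normal(n + 2000))[2000:]
    drift /= np.std(drift)

    row = np.sqrt(1 - drift_fraction**2) * rhythmic + drift_fraction * drift
    return rms * row / np.std(row)


def _artifact_ramps(
    n: int, fs: float, rms: float, breakpoint_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Slow piecewise-linear ramps, as produced by electrode/skin drift."""
    n_break = max(3, int(round(n / fs / breakpoint_s)) + 1)
    knots = np.sort(rng.uniform(0, n - 1, size=n_break))
    knots = np.concatenate([[0.0], knots, [n - 1.0]])
    levels = rng.standard_normal(knots.size)
    row = np.interp(np.arange(n), knots, levels)
    sd = np.std(row)
    if sd > 0:
        row = rms * row / sd
    return row


def generate_sources(
    events: EventSequence,
    duration: float,
    fs: float = 256.0,
    params: SourceParams | None = None,
    seed: int = 0,
) -> SourceSet:
    """Generate ground-truth source rows for an event schedule.

    Row 0 is the ERP source: a positive Gaussian template added at each
    target onset (peak at onset + 300 ms) plus a smaller early bump at
    non-target onsets. Background rows are rhythmic colored noise; the
    last row (optional) is a slow-ramp artifact. Every row is exactly
    zero-mean.
    """
    params = params or SourceParams()
    if len(events) and duration < events.onsets[-1] + 0.7:
        raise ValueError(
            f"duration {duration:.2f} s too short: need >= last onset + 0.7 s "
            f"({events.onsets[-1] + 0.7:.2f} s)"
        )
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)

    erp = _gaussian_bump_train(
        t, events.onsets[events.is_target], params.p300_latency, params.p300_sd,
        params.p300_uv,
    )
    erp += _gaussian_bump_train(
        t, events.onsets[~events.is_target], params.nontarget_latency,
        params.nontarget_sd, params.nontarget_ratio * params.p300_uv,
    )

    rows = [erp]
    kinds = ["erp"]
    for i in range(params.n_background):
        f0 = params.background_freqs[i % len(params.background_freqs)]
        r = params.background_radii[i % len(params.background_radii)]
        rows.append(
            _background(n, fs, f0, r, params.drift_fraction, params.background_uv, rng)
        )
        kinds.append("background")
    if params.include_artifact:
        rows.append(
            _artifact_ramps(n, fs, params.artifact_uv, params.artifact_breakpoint_s, rng)
        )
        kinds.append("artifact")

    S = np.vstack(rows)
    S -= S.mean(axis=1, keepdims=True)
    return SourceSet(S=S, kinds=tuple(kinds), fs=fs)


def make_mixing(
    M: int,
    N: int,
    seed: int = 0,
    cond_bound: float = 10.0,
    noise_sigma: float = 0.0,
    max_draws: int = 1000,
) -> MixtureModel:
    """Draw a random M x N mixing matrix with unit-norm columns.

    Matrices are re-drawn until the condition number is within
    ``cond_bound`` (full column rank is then automatic).
    """
    if M < N or N < 1:
        raise DimensionError(f"need M >= N >= 1, got M={M}, N={N}")
    rng = np.random.default_rng(seed)
    for _ in range(max_draws):
        A = rng.standard_normal((M, N))
        A /= np.linalg.norm(A, axis=0, keepdims=True)
        if np.linalg.cond(A) <= cond_bound:
            return MixtureModel(A=A, noise_sigma=noise_sigma, seed=seed)
    raise RuntimeError(
        f"no {M}x{N} matrix with condition number <= {cond_bound} in {max_draws} draws"
    )


def mix(sources: SourceSet, model: MixtureModel, seed: int = 0) -> Recording:
    """Form the sensor mixture ``X = A S + n`` (noise i.i.d. Gaussian)."""
    if model.n_sources != sources.n_sources:
        raise DimensionError(
            f"mixing has {model.n_sources} columns but {sources.n_sources} sources given"
        )
    X = model.A @ sources.S
    if model.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        X = X + model.noise_sigma * rng.standard_normal(X.shape)
    return Recording(X=X, fs=sources.fs)


def simulate_session(
    n_blocks: int = 12,
    isi: float = 0.350,
    flash_duration: float = 0.050,
    fs: float = 256.0,
    n_channels: int = 8,
    params: SourceParams | None = None,
    noise_sigma: float = 0.0,
    cond_bound: float = 10.0,
    seed: int = 0,
    duration: float | None = None,
) -> tuple[Recording, SourceSet, MixtureModel, EventSequence]:
    """Convenience wrapper generating one complete synthetic session.

    Sub-seeds for the schedule, sources, mixing, and sensor noise are
    derived deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_ev, s_src, s_mix, s_noise = [int(s) for s in ss.generate_state(4) % (2**31)]
    events = generate_stimulus_sequence(n_blocks, isi, flash_duration, seed=s_ev)
    if duration is None:
        duration = (events.onsets[-1] if len(events) else 0.0) + 1.0
    params = params or SourceParams()
    sources = generate_sources(events, duration, fs, params, seed=s_src)
    model = make_mixing(
        n_channels, sources.n_sources, seed=s_mix,
        cond_bound=cond_bound, noise_sigma=noise_sigma,
    )
    rec = mix(sources, model, seed=s_noise)
    return rec, sources, model, events
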