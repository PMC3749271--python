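"""Band-pass preprocessing and stimulus-locked epoch extraction.

EEG is filtered with a sixth-order Butterworth band-pass (1-12 Hz by
default): the low edge removes slow trends, the high edge discards
frequencies irrelevant to the P300. The default application is
forward-backward (zero phase) so the 300 ms peak latency is not distorted;
a causal single-pass mode is available for strict real-time semantics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from anpca.data import ConfigurationError, EpochSet, EventSequence, Recording

__all__ = ["FilterSpec", "bandpass", "frequency_response", "epoch_extract"]


@dataclass
class FilterSpec:
    """Band-pass filter description.

    ``order`` is the overall transfer-function order of the band-pass
    (must be even; a Butterworth band-pass of prototype order n has
    transfer-function order 2n).
    """

    order: int = 6
    low_hz: float = 1.0
    high_hz: float = 12.0
    design: str = "butterworth"
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if self.design != "butterworth":
            raise ConfigurationError(f"unsupported filter design {self.design!r}")
        if self.order < 2 or self.order % 2:
            raise ConfigurationError("filter order must be even and >= 2")
        if not (0 < self.low_hz < self.high_hz):
            raise ConfigurationError("need 0 < low_hz < high_hz")
        if self.high_hz >= fs / 2:
            raise ConfigurationError(
                f"high cut-off {self.high_hz} Hz not below Nyquist ({fs / 2} Hz)"
            )

    def sos(self, fs: float) -> np.ndarray:
        self.validate(fs)
        return signal.butter(
            self.order // 2, [self.low_hz, self.high_hz],
            btype="bandpass", fs=fs, output="sos",
        )


def bandpass(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Apply the band-pass to every channel of a recording."""
    spec = spec or FilterSpec()
    sos = spec.sos(rec.fs)
    if spec.zero_phase:
        Y = signal.sosfiltfilt(sos, rec.X, axis=1)
    else:
        Y = signal.sosfilt(sos, rec.X, axis=1)
    return rec.copy_with(Y)


def frequency_response(
    spec: FilterSpec, fs: float, freqs: np.ndarray
) -> np.ndarray:
    """Magnitude response of the *applied* filter at the given frequencies.

    For the zero-phase (forward-backward) mode this is the squared
    single-pass Butterworth magnitude.
    """
    _, h = signal.sosfreqz(spec.sos(fs), worN=np.asarray(freqs, float), fs=fs)
    mag = np.abs(h)
    return mag**2 if spec.zero_phase else mag


def epoch_extract(
    rec: Recording,
    events: EventSequence,
    window: tuple[float, float] = (0.0, 0.7),
    baseline: tuple[float, float] | None = (-0.1, 0.0),
) -> EpochSet:
    """Cut stimulus-locked windows and baseline-correct them.

    The onset sample is ``round(onset * fs)`` (0-based); the window is
    closed at both ends, so a [0, 0.7] s window at 256 Hz yields
    ``round(0.7 * 256) + 1 = 180`` samples. Baseline correction subtracts,
    per channel and epoch, the mean over the baseline interval (also a
    closed interval relative to onset); pass ``baseline=None`` to skip it.
    """
    fs = rec.fs
    w0 = int(round(window[0] * fs))
    w1 = int(round(window[1] * fs))
    if w1 < w0:
        raise ConfigurationError("window end before window start")
    onset_samples = np.round(events.onsets * fs).astype(int)

    starts = onset_samples + w0
    stops = onset_samples + w1
    bad = np.flatnonzero((starts < 0) | (stops >= rec.n_samples))
    if baseline is not None:
        b0 = int(round(baseline[0] * fs))
        b1 = int(round(baseline[1] * fs))
        bad = np.union1d(
            bad,
            np.flatnonzero((onset_samples + b0 < 0) | (onset_samples + b1 >= rec.n_samples)),
        )
    if bad.size:
        raise ValueError(
            f"epoch windows exceed recording bounds for events {bad.tolist()}"
        )

    n_win = w1 - w0 + 1
    data = np.empty((len(events), rec.n_channels, n_win))
    for i, s in enumerate(onset_samples):
        data[i] = rec.X[:, s + w0 : s + w1 + 1]
        if baseline is not None:
            base = rec.X[:, s + b0 : s + b1 + 1].mean(axis=1, keepdims=True)
            data[i] -= base
    return EpochSet(data=data, fs=fs, window=window, baseline=baseline, events=events)
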