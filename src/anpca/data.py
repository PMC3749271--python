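"""Core data containers for recordings, events, sources, and epochs.

Conventions
-----------
* Signals are ``channels x samples`` (or ``sources x samples``) float arrays
  in microvolts (µV).
* Time is in seconds; sample indices are 0-based with
  ``sample = round(t * fs)``.
* Every container validates its invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_CHANNELS = ("Fz", "Cz", "Pz", "Oz", "P7", "P3", "P4", "P8")

N_STIMULI = 7  # seven-choice oddball paradigm


class ConfigurationError(ValueError):
    """Raised when parameters are mutually inconsistent."""


class DimensionError(ValueError):
    """Raised when array shapes do not conform."""


@dataclass
class EventSequence:
    """Stimulus schedule of an oddball session.

    One *block* presents each of the seven stimuli exactly once in random
    order; the attended (target) stimulus is fixed for the whole session.

    Parameters
    ----------
    onsets : array of float
        Stimulus onset times in seconds, strictly increasing, spaced by
        ``isi``.
    stimulus_ids : array of int
        Stimulus identity, 1..7, one per onset.
    block_ids : array of int
        Block index (>= 0) of each event.
    target_id : int
        The attended stimulus id (1..7), constant over the session.
    flash_duration : float
        Image flash duration in seconds.
    isi : float
        Onset-to-onset inter-stimulus interval in seconds
        (``flash_duration + 0.300``).
    """

    onsets: np.ndarray
    stimulus_ids: np.ndarray
    block_ids: np.ndarray
    target_id: int
    flash_duration: float
    isi: float

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.stimulus_ids = np.asarray(self.stimulus_ids, dtype=int)
        self.block_ids = np.asarray(self.block_ids, dtype=int)
        n = self.onsets.size
        if self.stimulus_ids.size != n or self.block_ids.size != n:
            raise DimensionError("onsets, stimulus_ids, block_ids must have equal length")
        if abs(self.flash_duration + 0.300 - self.isi) > 1e-3:
            raise ConfigurationError(
                f"flash_duration ({self.flash_duration}) + 0.300 s blank must equal "
                f"isi ({self.isi}) within 1 ms"
            )
        if n:
            d = np.diff(self.onsets)
            if np.any(d <= 0):
                raise ValueError("onsets must be strictly increasing")
            if not (1 <= self.target_id <= N_STIMULI):
                raise ValueError("target_id must be in 1..7")
            for b in np.unique(self.block_ids):
                ids = np.sort(self.stimulus_ids[self.block_ids == b])
                if not np.array_equal(ids, np.arange(1, N_STIMULI + 1)):
                    raise ValueError(f"block {b} must contain each stimulus id exactly once")

    def __len__(self) -> int:
        return int(self.onsets.size)

    @property
    def n_blocks(self) -> int:
        return int(np.unique(self.block_ids).size)

    @property
    def is_target(self) -> np.ndarray:
        """Boolean mask of target events."""
        return self.stimulus_ids == self.target_id

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with columns onset/stimulus/block/is_target."""
        return pd.DataFrame(
            {
                "onset": self.onsets,
                "stimulus": self.stimulus_ids,
                "block": self.block_ids,
                "is_target": self.is_target.astype(int),
            }
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, flash_duration: float, isi: float
    ) -> "EventSequence":
        if len(df) == 0:
            target = 1
        else:
            targets = np.unique(df.loc[df["is_target"] == 1, "stimulus"])
            if targets.size != 1:
                raise ValueError("event table must mark exactly one target stimulus id")
            target = int(targets[0])
        return cls(
            onsets=df["onset"].to_numpy(float),
            stimulus_ids=df["stimulus"].to_numpy(int),
            block_ids=df["block"].to_numpy(int),
            target_id=target,
            flash_duration=flash_duration,
            isi=isi,
        )


@dataclass
class SourceSet:
    """Ground-truth source signals, one row per source, in µV."""

    S: np.ndarray
    kinds: tuple[str, ...]
    fs: float

    def __post_init__(self) -> None:
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        if self.S.shape[0] < 1:
            raise DimensionError("need at least one source")
        if len(self.kinds) != self.S.shape[0]:
            raise DimensionError("one kind per source row required")
        bad = set(self.kinds) - {"erp", "background", "artifact"}
        if bad:
            raise ValueError(f"unknown source kinds: {bad}")
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")

    @property
    def n_sources(self) -> int:
        return self.S.shape[0]

    @property
    def n_samples(self) -> int:
        return self.S.shape[1]


@dataclass
class MixtureModel:
    """Linear instantaneous mixing model ``x = A s + n``.

    ``A`` is M x N with unit-norm columns and full column rank; ``noise_sigma``
    is the per-sample standard deviation (µV) of the additive white Gaussian
    sensor noise.
    """

    A: np.ndarray
    noise_sigma: float
    seed: int

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2:
            raise DimensionError("A must be a matrix")
        if np.linalg.matrix_rank(self.A) < self.A.shape[1]:
            raise ValueError("mixing matrix must have full column rank")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")

    @property
    def n_channels(self) -> int:
        return self.A.shape[0]

    @property
    def n_sources(self) -> int:
        return self.A.shape[1]

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.A))


@dataclass
class Recording:
    """Multichannel potential recording, ``channels x samples`` in µV."""

    X: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = field(default=DEFAULT_CHANNELS)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if not np.all(np.isfinite(self.X)):
            raise ValueError("recording contains non-finite values")
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")
        labels = tuple(self.channel_labels)
        if len(labels) != self.X.shape[0]:
            # fall back to generated labels when the defaults do not fit
            if self.channel_labels == DEFAULT_CHANNELS:
                labels = tuple(f"ch{i}" for i in range(self.X.shape[0]))
            else:
                raise DimensionError(
                    f"{len(labels)} labels for {self.X.shape[0]} channels"
                )
        self.channel_labels = labels

    @property
    def n_channels(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy_with(self, X: np.ndarray) -> "Recording":
        return Recording(X=X, fs=self.fs, channel_labels=self.channel_labels)


@dataclass
class EpochSet:
    """Stimulus-locked signal windows: ``events x channels x samples``.

    ``window`` and ``baseline`` are (start, end) intervals in seconds
    relative to stimulus onset; both ends are inclusive.
    """

    data: np.ndarray
    fs: float
    window: tuple[float, float]
    baseline: tuple[float, float] | None
    events: EventSequence

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise DimensionError("epoch tensor must be events x channels x samples")
        if self.data.shape[0] != len(self.events):
            raise DimensionError("epoch count must match event count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Sample times relative to onset."""
        n = self.data.shape[2]
        return self.window[0] + np.arange(n) / self.fs
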