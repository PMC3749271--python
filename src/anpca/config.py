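"""Declarative session configuration for the command-line pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from anpca.data import ConfigurationError

__all__ = ["SessionConfig", "load_config"]


@dataclass
class SessionConfig:
    """Every tunable of the pipeline in one declarative object.

    Defaults are the reference study conditions: a single replayed block of
    7000 samples with learning parameters beta=0.6 (online tracker),
    xi=0.01 (whitening), gamma=0.002 (separation), alpha=0.3 (estimation).
    """

    seed: int = 0
    block_length: int = 7000

    synth: dict = field(default_factory=lambda: {
        "n_blocks": 12, "isi": 0.350, "flash_duration": 0.050,
        "fs": 256.0, "n_channels": 8, "noise_sigma": 0.0, "cond_bound": 10.0,
    })
    filter: dict = field(default_factory=lambda: {
        "order": 6, "low_hz": 1.0, "high_hz": 12.0, "zero_phase": True,
    })
    preseparation: dict = field(default_factory=lambda: {
        "tau": list(range(1, 33)), "beta": 0.6, "n_keep": "auto",
    })
    whitening: dict = field(default_factory=lambda: {
        "xi": 0.01, "eta0": 0.1, "block": 256, "tol": 0.05,
    })
    separation: dict = field(default_factory=lambda: {
        "gamma": 0.002, "mu0": 0.1, "rule": "printed",
        "ortho_every": 100, "passes": 10,
    })
    estimation: dict = field(default_factory=lambda: {"alpha": 0.3})
    mnn: dict = field(default_factory=lambda: {
        "enabled": False, "hidden": None, "bottleneck": 2, "epochs": 200,
    })

    def validate(self) -> None:
        for name, value in (
            ("whitening.xi", self.whitening["xi"]),
            ("separation.gamma", self.separation["gamma"]),
        ):
            if not (0 < value <= 1):
                raise ConfigurationError(f"{name} must be in (0, 1], got {value}")
        for name, value in (
            ("preseparation.beta", self.preseparation["beta"]),
            ("whitening.eta0", self.whitening["eta0"]),
            ("separation.mu0", self.separation["mu0"]),
            ("estimation.alpha", self.estimation["alpha"]),
        ):
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        if self.block_length < 2 * self.synth["n_channels"]:
            raise ConfigurationError("block_length must be at least twice the channel count")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path=None, **overrides) -> SessionConfig:
    """Load a YAML config (missing keys fall back to defaults)."""
    cfg = SessionConfig()
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    for key, value in data.items():
        if not hasattr(cfg, key):
            raise ConfigurationError(f"unknown config key {key!r}")
        current = getattr(cfg, key)
        if isinstance(current, dict) and isinstance(value, dict):
            unknown = set(value) - set(current)
            if unknown:
                raise ConfigurationError(f"unknown keys under {key!r}: {sorted(unknown)}")
            current.update(value)
        else:
            setattr(cfg, key, value)
    cfg.validate()
    return cfg
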