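"""File I/O: delimited matrices, EDF, event tables, and ground truth.

Delimited recordings are one channel per row with an optional leading
header row of channel labels; a sidecar is not needed because the sampling
rate travels in the function signature (the CLI keeps it in the session
config). EDF reading goes through MNE; writing uses a minimal EDF
(16-bit) encoder sufficient for integer sampling rates, which MNE reads
back verbatim (this round trip is exercised in the test suite).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from anpca.data import EventSequence, MixtureModel, Recording, SourceSet

__all__ = [
    "write_delimited",
    "read_delimited",
    "write_edf",
    "read_edf",
    "read_recording",
    "write_recording",
    "write_events",
    "read_events",
    "write_truth",
    "read_truth",
    "provenance_block",
]


# ---------------------------------------------------------------------------
# Delimited text
# ---------------------------------------------------------------------------

def write_delimited(rec: Recording, path, delimiter: str = "\t", header: bool = True) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header:
            fh.write(delimiter.join(rec.channel_labels) + "\n")
        for row in rec.X:
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")


def read_delimited(path, fs: float, delimiter: str = "\t") -> Recording:
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    first = lines[0].split(delimiter)
    labels = None
    start = 0
    try:
        float(first[0])
    except ValueError:
        labels = tuple(s.strip() for s in first)
        start = 1
    rows = []
    for i, ln in enumerate(lines[start:], start=start + 1):
        try:
            rows.append([float(v) for v in ln.split(delimiter)])
        except ValueError as exc:
            raise ValueError(f"{path}: cannot parse line {i}: {exc}") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows (widths {sorted(widths)})")
    X = np.asarray(rows)
    if labels is not None and len(labels) != X.shape[0]:
        raise ValueError(f"{path}: {len(labels)} labels for {X.shape[0]} channel rows")
    if labels is None:
        return Recording(X=X, fs=fs)
    return Recording(X=X, fs=fs, channel_labels=labels)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path) -> None:
    """Write a recording as a 16-bit EDF file (µV physical units).

    Requires an integer sampling rate; one data record per second, the
    last record zero-padded when the duration is fractional.
    """
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    ns = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / fs))
    pad = n_rec * fs - rec.n_samples
    X = np.pad(rec.X, ((0, 0), (0, pad)))

    pmin = np.floor(X.min(axis=1))
    pmax = np.ceil(X.max(axis=1))
    pmax = np.where(pmax <= pmin, pmin + 1, pmax)
    dmin, dmax = -32768, 32767
    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.round((X - pmin[:, None]) * gain[:, None] + dmin).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii("Startdate 01-JAN-2000 X X X", 80),
            _ascii(now.strftime("%d.%m.%y"), 8),
            _ascii(now.strftime("%H.%M.%S"), 8),
            _ascii(256 * (ns + 1), 8),
            _ascii("", 44),
            _ascii(n_rec, 8),
            _ascii(1, 8),
            _ascii(ns, 4),
        ]
    )
    fields = [
        (16, list(rec.channel_labels)),
        (80, [""] * ns),
        (8, ["uV"] * ns),
        (8, [f"{v:g}" for v in pmin]),
        (8, [f"{v:g}" for v in pmax]),
        (8, [dmin] * ns),
        (8, [dmax] * ns),
        (80, [""] * ns),
        (8, [fs] * ns),
        (32, [""] * ns),
    ]
    sig_header = b"".join(
        b"".join(_ascii(v, width) for v in values) for width, values in fields
    )
    with Path(path).open("wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_rec):
            chunk = digital[:, r * fs : (r + 1) * fs]
            fh.write(chunk.tobytes())  # channel-major within each record


def read_edf(path) -> Recording:
    """Read an EDF file (via MNE), returning potentials in µV."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    X = raw.get_data() * 1e6  # MNE uses volts internally
    return Recording(X=X, fs=float(raw.info["sfreq"]), channel_labels=tuple(raw.ch_names))


def read_recording(path, fs: float | None = None, fmt: str | None = None) -> Recording:
    """Dispatch on format/extension (``.edf`` or delimited text)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or ("edf" if path.suffix.lower() == ".edf" else "delimited")
    if fmt == "edf":
        return read_edf(path)
    if fs is None:
        raise ValueError("sampling rate required for delimited recordings")
    return read_delimited(path, fs=fs)


def write_recording(rec: Recording, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or ("edf" if path.suffix.lower() == ".edf" else "delimited")
    if fmt == "edf":
        write_edf(rec, path)
    else:
        write_delimited(rec, path)


# ---------------------------------------------------------------------------
# Events and ground truth
# ---------------------------------------------------------------------------

def write_events(events: EventSequence, path) -> None:
    """Tab-separated event table with onset/stimulus/block/is_target."""
    df = events.to_frame()
    with Path(path).open("w") as fh:
        fh.write(f"# flash_duration={events.flash_duration:.3f}\tisi={events.isi:.3f}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_events(path) -> EventSequence:
    path = Path(path)
    first = path.open().readline()
    meta = {}
    skip = 0
    if first.startswith("#"):
        skip = 1
        for tok in first[1:].split():
            k, _, v = tok.partition("=")
            meta[k] = float(v)
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    return EventSequence.from_frame(
        df,
        flash_duration=meta.get("flash_duration", 0.050),
        isi=meta.get("isi", 0.350),
    )


def write_truth(path, sources: SourceSet, model: MixtureModel) -> None:
    """Sidecar archive with ground-truth sources and mixing for scoring."""
    np.savez_compressed(
        path, S=sources.S, kinds=np.asarray(sources.kinds), fs=sources.fs,
        A=model.A, noise_sigma=model.noise_sigma, seed=model.seed,
    )


def read_truth(path) -> tuple[SourceSet, MixtureModel]:
    with np.load(path, allow_pickle=False) as z:
        sources = SourceSet(S=z["S"], kinds=tuple(str(k) for k in z["kinds"]), fs=float(z["fs"]))
        model = MixtureModel(A=z["A"], noise_sigma=float(z["noise_sigma"]), seed=int(z["seed"]))
    return sources, model


# ---------------------------------------------------------------------------
# Provenance
# ---------------------------------------------------------------------------

def provenance_block(config: dict, seed: int) -> dict:
    """Machine-readable reproduction record for a CLI run."""
    import anpca

    payload = json.dumps(config, sort_keys=True, default=str)
    return {
        "config_hash": hashlib.sha256(payload.encode()).hexdigest(),
        "config": config,
        "seed": seed,
        "anpca_version": anpca.__version__,
        "numpy_version": np.__version__,
        "python_version": sys.version.split()[0],
    }
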