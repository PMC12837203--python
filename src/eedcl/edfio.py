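"""Minimal European Data Format (EDF) writer and an mne-backed reader.

EDF stores each signal as 16-bit integers with a per-signal linear mapping
between digital and physical units.  The writer emits one-second data
records, which covers the integer-rate recordings produced by the synthetic
generator; reading goes through :func:`mne.io.read_raw_edf` so that the
round trip is checked against an independent implementation.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

from .types import Recording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    for fmt in (f"%.{width - 2}g", "%.4g", "%.3g", "%.2g"):
        s = (fmt % value)
        if len(s) <= width:
            return _field(s, width)
    raise ValueError(f"cannot format {value} in {width} chars")


def write_edf(path: str | Path, rec: Recording) -> Path:
    """Write a recording to EDF (µV physical units, 1 s data records).

    Requires an integer sampling rate and an integer number of seconds;
    the synthetic generator produces both.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_rec, rem = divmod(rec.n_samples, fs)
    if rem:
        raise ValueError("EDF writer requires a whole number of seconds")
    c = rec.n_channels

    x = rec.samples
    span = np.abs(x).max(axis=1)
    span = np.where(span <= 0, 1.0, span * 1.0001)
    pmin, pmax = -span, span
    scale = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
    digital = np.rint((x - pmin[:, None]) / scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _field("0", 8),
        _field(f"X X X {rec.subject_id or 'X'}", 80),
        _field(f"Startdate 01-JAN-2000 X X X trial_{rec.trial_id or 'X'}", 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field(now.strftime("%H.%M.%S"), 8),
        _field(str(256 * (1 + c)), 8),
        _field("", 44),
        _field(str(n_rec), 8),
        _field("1", 8),
        _field(str(c), 4),
    ])
    labels = [lb[:16] for lb in rec.channel_labels]
    header += b"".join(_field(lb, 16) for lb in labels)
    header += b"".join(_field("", 80) for _ in range(c))
    header += b"".join(_field("uV", 8) for _ in range(c))
    header += b"".join(_num(pmin[i], 8) for i in range(c))
    header += b"".join(_num(pmax[i], 8) for i in range(c))
    header += b"".join(_field(str(_DIG_MIN), 8) for _ in range(c))
    header += b"".join(_field(str(_DIG_MAX), 8) for _ in range(c))
    header += b"".join(_field("", 80) for _ in range(c))
    header += b"".join(_field(str(fs), 8) for _ in range(c))
    header += b"".join(_field("", 32) for _ in range(c))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())
    return path


def quantization_step(rec: Recording) -> np.ndarray:
    """Per-channel physical value of one digital unit for :func:`write_edf`."""
    span = np.abs(rec.samples).max(axis=1)
    span = np.where(span <= 0, 1.0, span * 1.0001)
    return 2 * span / (_DIG_MAX - _DIG_MIN)


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file via mne; returns samples in microvolts."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such EDF file: {path}")
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    samples = raw.get_data() * 1e6          # mne scales EEG channels to volts
    patient = raw.info.get("subject_info") or {}
    subject = patient.get("last_name") or ""
    return Recording(samples=samples, fs=float(raw.info["sfreq"]),
                     channel_labels=list(raw.ch_names), subject_id=subject)
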