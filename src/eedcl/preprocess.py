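"""Preprocessing pipeline: bandpass → re-reference → z-score → segment.

The filter is a 4th-order Butterworth applied forward–backward
(zero-phase).  Two band conventions circulate for this kind of affective
EEG work — a 4–47 Hz band and a wider 0.5–50 Hz band — so both are plain
arguments here, with 4–47 Hz as the default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .types import Recording, Segment

log = logging.getLogger(__name__)

DEFAULT_BAND = (4.0, 47.0)
ALT_BAND = (0.5, 50.0)


def bandpass(rec: Recording, low_hz: float = DEFAULT_BAND[0],
             high_hz: float = DEFAULT_BAND[1], order: int = 4) -> Recording:
    """Zero-phase Butterworth bandpass."""
    nyq = rec.fs / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"band edges must satisfy 0 < {low_hz} < {high_hz} < fs/2={nyq}")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs,
                     output="sos")
    return rec.with_samples(sps.sosfiltfilt(sos, rec.samples, axis=1))


def rereference(rec: Recording, scheme: str = "common_average") -> Recording:
    """Re-reference; common average subtracts the instantaneous channel mean."""
    if scheme != "common_average":
        raise ValueError(f"unknown re-referencing scheme {scheme!r}")
    if rec.n_channels < 2:
        raise ValueError("common-average reference requires >= 2 channels")
    return rec.with_samples(rec.samples - rec.samples.mean(axis=0, keepdims=True))


def zscore(rec: Recording, zero_variance: str = "leave") -> Recording:
    """Per-channel standardization to mean 0, sd 1.

    ``zero_variance``: 'leave' centres a constant channel at zero (with a
    warning); 'error' raises instead.
    """
    mu = rec.samples.mean(axis=1, keepdims=True)
    sd = rec.samples.std(axis=1, keepdims=True)
    flat = (sd.ravel() == 0)
    if flat.any():
        if zero_variance == "error":
            raise ValueError(f"zero-variance channels: {np.flatnonzero(flat)}")
        warnings.warn(f"{flat.sum()} zero-variance channel(s) left at zero")
        sd[sd == 0] = 1.0
    return rec.with_samples((rec.samples - mu) / sd)


def segment(rec: Recording, win_s: float = 4.0,
            overlap: float = 0.5) -> list[Segment]:
    """Sliding windows of ``win_s`` seconds; remainder samples are dropped.

    Windows are sample-indexed, 0-based, half-open [start, start + W).
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    w = int(round(win_s * rec.fs))
    hop = int(round(w * (1.0 - overlap)))
    if hop < 1:
        raise ValueError("hop must be at least one sample")
    if rec.n_samples < w:
        warnings.warn(
            f"recording shorter than one window ({rec.n_samples} < {w})")
        return []
    count = (rec.n_samples - w) // hop + 1
    return [
        Segment(samples=rec.samples[:, i * hop:i * hop + w], fs=rec.fs,
                t_start=i * hop / rec.fs, subject_id=rec.subject_id,
                trial_id=rec.trial_id, class_label=rec.class_label)
        for i in range(count)
    ]


@dataclass
class PreprocessConfig:
    low_hz: float = DEFAULT_BAND[0]
    high_hz: float = DEFAULT_BAND[1]
    order: int = 4
    reref: str = "common_average"
    win_s: float = 4.0
    overlap: float = 0.5


def preprocess_recording(rec: Recording,
                         cfg: PreprocessConfig | None = None) -> list[Segment]:
    """Full pipeline on one recording; returns its segments."""
    cfg = cfg or PreprocessConfig()
    rec = bandpass(rec, cfg.low_hz, cfg.high_hz, cfg.order)
    if cfg.reref is not None and rec.n_channels >= 2:
        rec = rereference(rec, cfg.reref)
    rec = zscore(rec)
    return segment(rec, cfg.win_s, cfg.overlap)


def preprocess_dataset(recordings: list[Recording],
                       cfg: PreprocessConfig | None = None) -> list[Segment]:
    segs: list[Segment] = []
    for rec in recordings:
        segs.extend(preprocess_recording(rec, cfg))
    return segs


def manifest(segments: list[Segment]):
    """Per-segment manifest as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [{"subject_id": s.subject_id, "trial_id": s.trial_id,
          "t_start": s.t_start, "class": s.class_label} for s in segments])
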