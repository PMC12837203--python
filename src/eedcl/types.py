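"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np


@dataclass
class Recording:
    """Multichannel EEG recording.

    samples : (channels, time) array in microvolts (or z-units after
        normalization); fs : sampling rate in Hz.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = ""
    trial_id: str = ""
    class_label: Optional[int] = None

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.isfinite(self.samples).all():
            raise ValueError("recording contains non-finite samples")
        if not self.channel_labels:
            self.channel_labels = [f"EEG{i:03d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel label count mismatch")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray) -> "Recording":
        return replace(self, samples=samples)


@dataclass
class Segment:
    """One fixed-length analysis window cut from a recording."""

    samples: np.ndarray
    fs: float
    t_start: float = 0.0
    subject_id: str = ""
    trial_id: str = ""
    class_label: Optional[int] = None

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if not np.isfinite(self.samples).all():
            raise ValueError("segment contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def with_samples(self, samples: np.ndarray) -> "Segment":
        return replace(self, samples=samples)


def segments_to_batch(segments: list[Segment]) -> np.ndarray:
    """Stack segments into a (N, channels, window) float32 batch."""
    return np.stack([s.samples for s in segments]).astype(np.float32)
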