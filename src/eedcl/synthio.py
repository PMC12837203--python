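"""Synthetic multi-subject EEG with planted class-dependent band power.

The generator emulates the signal properties the downstream model is built
to exploit: oscillatory sources confined to the canonical theta (4–8 Hz),
alpha (8–13 Hz) and beta (13–30 Hz) bands, mixed into channels through a
per-subject spatial mixing matrix, scaled by per-subject channel gains, on
top of 1/f ("pink") background noise.  Class identity acts multiplicatively
on the theta and alpha source amplitudes — mirroring the band-power shifts
that distinguish affective/fatigue states in scalp EEG — so a band-power
oracle can verify that the planted effect is recoverable before any
learning is attempted.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .edfio import write_edf
from .types import Recording

BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}
#: bands whose source amplitude is scaled by the class factor
CLASS_BANDS = ("theta", "alpha")
_SOURCES_PER_BAND = 2
_GAIN_BOUNDS = (0.5, 2.0)


@dataclass
class SubjectProfile:
    """Per-subject signal parameters (gains, mixing, band amplitudes)."""

    subject_id: str
    channel_gains: np.ndarray            # (C,) positive scale factors
    spatial_mixing: np.ndarray           # (C, n_sources) mixing weights
    baseline_band_amps: dict[str, float]
    noise_level: float = 1.0

    def __post_init__(self):
        self.channel_gains = np.asarray(self.channel_gains, dtype=np.float64)
        self.spatial_mixing = np.atleast_2d(
            np.asarray(self.spatial_mixing, dtype=np.float64))
        if (self.channel_gains <= 0).any():
            raise ValueError("channel_gains must be positive")
        if not np.isfinite(self.spatial_mixing).all():
            raise ValueError("spatial_mixing must be finite")
        if any(v < 0 for v in self.baseline_band_amps.values()):
            raise ValueError("baseline_band_amps must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.channel_gains.size


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic bench (DEAP-like geometry)."""

    n_subjects: int = 3
    n_classes: int = 2
    trials_per_class: int = 40
    n_channels: int = 32
    duration_s: float = 60.0
    fs: float = 128.0
    class_effect: float = 2.0            # amplitude factor between extreme classes
    noise_level: float = 1.0
    phase_coherence_s: float = 1.0       # source phase coherence time (0 = locked)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_subjects, self.n_classes, self.trials_per_class,
               self.n_channels) < 1:
            raise ValueError("all counts must be >= 1")
        if self.class_effect <= 0:
            raise ValueError("class_effect must be positive")
        top = max(hi for _, hi in BANDS.values())
        if self.fs <= 2 * top:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest band edge ({top} Hz)")

    def class_factor(self, class_label: int) -> float:
        """Geometric spacing: extreme classes differ by ``class_effect``."""
        if self.n_classes == 1:
            return 1.0
        expo = class_label / (self.n_classes - 1)
        return float(self.class_effect ** expo)


def make_subject_profile(seed: int, n_channels: int,
                         noise_level: float = 1.0) -> SubjectProfile:
    """Draw a deterministic subject profile from ``seed``."""
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([834_001, int(seed)]))
    gains = rng.uniform(*_GAIN_BOUNDS, size=n_channels)
    n_sources = _SOURCES_PER_BAND * len(BANDS)
    mixing = rng.normal(0.0, 1.0, size=(n_channels, n_sources))
    mixing /= np.sqrt(_SOURCES_PER_BAND)
    amps = {
        "theta": 0.8 * rng.uniform(0.8, 1.25),
        "alpha": 1.0 * rng.uniform(0.8, 1.25),
        "beta": 0.5 * rng.uniform(0.8, 1.25),
    }
    return SubjectProfile(subject_id=f"S{int(seed):03d}", channel_gains=gains,
                          spatial_mixing=mixing, baseline_band_amps=amps,
                          noise_level=noise_level)


def _pink_noise(rng: np.random.Generator, n_channels: int, n: int,
                fs: float) -> np.ndarray:
    """Unit-RMS 1/f-power noise via spectral shaping of white noise."""
    white = rng.normal(size=(n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    freqs[0] = freqs[1]
    spec *= freqs ** -0.5                 # power density ∝ 1/f
    out = np.fft.irfft(spec, n=n, axis=1)
    rms = out.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return out / rms


def generate_recording(profile: SubjectProfile, class_label: int,
                       cfg: GeneratorConfig, trial: int = 0,
                       band_freqs: dict[str, list[float]] | None = None,
                       ) -> Recording:
    """Synthesize one trial for ``profile`` with the class-scaled band mix.

    ``band_freqs`` pins the source frequencies (one list per band) instead of
    drawing them at random — used by spectral oracle tests.
    """
    if not 0 <= class_label < cfg.n_classes:
        raise ValueError(f"class_label {class_label} out of range")
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    subj_key = zlib.crc32(profile.subject_id.encode()) % (2 ** 31)
    rng = np.random.default_rng(np.random.SeedSequence(
        [291_117, int(cfg.seed), subj_key, int(class_label), int(trial)]))

    factor = cfg.class_factor(class_label)
    sources = np.zeros((profile.spatial_mixing.shape[1], n))
    idx = 0
    for band, (lo, hi) in BANDS.items():
        amp = profile.baseline_band_amps[band]
        if band in CLASS_BANDS:
            amp *= factor
        for k in range(_SOURCES_PER_BAND):
            if band_freqs is not None:
                freqs = band_freqs.get(band, [])
                f = freqs[k % len(freqs)] if freqs else 0.0
            else:
                f = rng.uniform(lo, hi)
            phase = rng.uniform(0, 2 * np.pi)
            if f > 0:
                # sqrt(2): unit-RMS sinusoid, so amp is an RMS amplitude
                arg = 2 * np.pi * f * t + phase
                if cfg.phase_coherence_s > 0:
                    # phase diffusion: cortical rhythms hold phase for ~1 s,
                    # not a whole trial; random-walk increments sized so the
                    # autocorrelation decays with time constant tau_c
                    sig = np.sqrt(2.0 / (cfg.phase_coherence_s * cfg.fs))
                    arg = arg + np.cumsum(rng.normal(0.0, sig, size=n))
                sources[idx] = amp * np.sqrt(2.0) * np.sin(arg)
            idx += 1

    x = profile.spatial_mixing @ sources
    noise = cfg.noise_level * profile.noise_level
    if noise > 0:
        x = x + noise * _pink_noise(rng, profile.n_channels, n, cfg.fs)
    x *= profile.channel_gains[:, None]
    return Recording(samples=x, fs=cfg.fs,
                     subject_id=profile.subject_id,
                     trial_id=f"{profile.subject_id}_c{class_label}_t{trial:03d}",
                     class_label=class_label)


def generate_dataset(cfg: GeneratorConfig) -> list[Recording]:
    """Full factorial subjects × classes × trials, balanced by construction."""
    recordings = []
    for s in range(cfg.n_subjects):
        profile = make_subject_profile(cfg.seed * 1000 + s, cfg.n_channels,
                                       noise_level=1.0)
        for c in range(cfg.n_classes):
            for k in range(cfg.trials_per_class):
                recordings.append(generate_recording(profile, c, cfg, trial=k))
    return recordings


def write_fixture(dataset: list[Recording], directory: str | Path) -> Path:
    """Write one EDF per recording plus a ``labels.csv`` table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in dataset:
        write_edf(directory / f"{rec.trial_id}.edf", rec)
        rows.append((rec.subject_id, rec.trial_id, rec.class_label))
    with open(directory / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "trial_id", "class"])
        writer.writerows(rows)
    return directory


def read_fixture(directory: str | Path) -> list[Recording]:
    """Load a fixture directory written by :func:`write_fixture`."""
    from .edfio import read_edf

    directory = Path(directory)
    out = []
    with open(directory / "labels.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            rec = read_edf(directory / f"{row['trial_id']}.edf")
            rec.subject_id = row["subject_id"]
            rec.trial_id = row["trial_id"]
            rec.class_label = int(row["class"])
            out.append(rec)
    return out
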