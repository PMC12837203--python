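"""Segment augmentations and contrastive pair construction.

Augmentations operate on z-scored segments: additive Gaussian noise,
window shifting within the parent recording, and smooth monotone time
warping.  Pair construction supports two modes: ``class_conditioned``
(positives share subject and class, negatives differ in class) and
``self_supervised`` (positives are two augmented views of the same
segment; negatives are other segments, preferring other subjects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .types import Recording, Segment


@dataclass
class AugmentConfig:
    noise_sigma: float = 0.1         # sd in units of the z-scored signal
    shift_window_s: float = 4.0
    shift_overlap: tuple[float, float] = (0.3, 0.5)
    warp_max: float = 0.10           # fractional time distortion
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 <= self.warp_max < 1:
            raise ValueError("warp_max must be in [0, 1)")


@dataclass
class ContrastiveBatch:
    anchors: list[Segment]
    positives: list[Segment]
    negatives: list[list[Segment]]
    pair_mode: str = "class_conditioned"

    def __post_init__(self):
        if len(self.anchors) != len(self.positives):
            raise ValueError("anchors and positives must pair up")


def add_gaussian_noise(seg: Segment, sigma: float,
                       rng: np.random.Generator) -> Segment:
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return seg
    return seg.with_samples(seg.samples + rng.normal(0.0, sigma,
                                                     size=seg.samples.shape))


def window_shift(seg: Segment, parent: Recording, cfg: AugmentConfig,
                 rng: np.random.Generator,
                 overlap: float | None = None) -> Segment:
    """Redraw the window at an offset overlapping the anchor window.

    The overlap fraction is sampled from ``cfg.shift_overlap`` unless pinned
    by ``overlap``; shift direction is random.  Falls back to the identity
    (with a warning) when the parent cannot host the shifted window.
    """
    w = seg.n_samples
    if overlap is None:
        overlap = float(rng.uniform(*cfg.shift_overlap))
    shift = int(round(w * (1.0 - overlap))) * (1 if rng.random() < 0.5 else -1)
    start = int(round(seg.t_start * parent.fs)) + shift
    if start < 0 or start + w > parent.n_samples:
        start = int(round(seg.t_start * parent.fs)) - shift
    if start < 0 or start + w > parent.n_samples:
        warnings.warn("parent too short for window shift; returning anchor")
        return seg
    return Segment(samples=parent.samples[:, start:start + w], fs=seg.fs,
                   t_start=start / parent.fs, subject_id=seg.subject_id,
                   trial_id=seg.trial_id, class_label=seg.class_label)


def _warp_map(n: int, warp_max: float, rng: np.random.Generator,
              rates: list[float] | None, preserve_duration: bool,
              n_knots: int = 4) -> np.ndarray:
    """Monotone piecewise-linear source positions for ``n`` output samples."""
    if rates is None:
        rates = rng.uniform(1.0 - warp_max, 1.0 + warp_max, size=n_knots)
    rates = np.clip(np.asarray(rates, dtype=np.float64),
                    1.0 - warp_max if warp_max > 0 else 0.0, None)
    edges = np.linspace(0, n - 1, len(rates) + 1)
    seg_len = np.diff(edges)
    advance = rates * seg_len
    if preserve_duration and advance.sum() > 0:
        advance *= (n - 1) / advance.sum()
    cum = np.concatenate([[0.0], np.cumsum(advance)])
    pos = np.interp(np.arange(n, dtype=np.float64), edges, cum)
    return np.clip(pos, 0.0, n - 1)


def time_warp(seg: Segment, warp_max: float, rng: np.random.Generator,
              rates: list[float] | None = None,
              preserve_duration: bool = True) -> Segment:
    """Resample along a smooth monotone time map (local rate within
    ``1 ± warp_max``); output length equals input length.

    With ``preserve_duration`` the knot rates are renormalized so the map
    ends where the signal ends; pass ``preserve_duration=False`` with
    explicit ``rates`` to apply a uniform stretch (edge-held) instead.
    """
    if not 0 <= warp_max < 1:
        raise ValueError("warp_max must be in [0, 1)")
    n = seg.n_samples
    if warp_max == 0 and rates is None:
        return seg
    pos = _warp_map(n, warp_max, rng, rates, preserve_duration)
    t = np.arange(n, dtype=np.float64)
    out = np.stack([np.interp(pos, t, ch) for ch in seg.samples])
    return seg.with_samples(out)


def augment_view(seg: Segment, cfg: AugmentConfig, rng: np.random.Generator,
                 parent: Recording | None = None) -> Segment:
    """One stochastic augmentation pass: (shift) → warp → noise."""
    out = seg
    if parent is not None:
        out = window_shift(out, parent, cfg, rng)
    if cfg.warp_max > 0:
        out = time_warp(out, cfg.warp_max, rng)
    return add_gaussian_noise(out, cfg.noise_sigma, rng)


def make_pairs(segments: list[Segment], mode: str, cfg: AugmentConfig,
               rng: np.random.Generator,
               n_negatives: int | None = None) -> ContrastiveBatch:
    """Build a contrastive batch from labelled (or unlabelled) segments.

    ``n_negatives`` caps negatives per anchor; default uses every eligible
    in-batch segment as a negative.
    """
    if mode not in ("class_conditioned", "self_supervised"):
        raise ValueError(f"unknown pair mode {mode!r}")
    anchors, positives, negatives = [], [], []

    if mode == "class_conditioned":
        if any(s.class_label is None for s in segments):
            raise ValueError("class_conditioned pairing requires labels")
        keys = [(s.subject_id, s.class_label) for s in segments]
        for i, seg in enumerate(segments):
            mates = [j for j, k in enumerate(keys)
                     if k == keys[i] and j != i]
            if not mates:
                warnings.warn(
                    f"segment {i} has no same-(subject, class) mate; skipped")
                continue
            pos = segments[int(rng.choice(mates))]
            negs = [segments[j] for j, s in enumerate(segments)
                    if s.class_label != seg.class_label]
            if not negs:
                warnings.warn(f"segment {i} has no negatives; skipped")
                continue
            anchors.append(augment_view(seg, cfg, rng))
            positives.append(augment_view(pos, cfg, rng))
            if n_negatives is not None and len(negs) > n_negatives:
                idx = rng.choice(len(negs), size=n_negatives, replace=False)
                negs = [negs[int(j)] for j in idx]
            negatives.append(negs)
    else:
        for i, seg in enumerate(segments):
            negs = [s for j, s in enumerate(segments)
                    if j != i and (s.subject_id != seg.subject_id
                                   or s.trial_id != seg.trial_id)]
            if not negs:
                warnings.warn(f"segment {i} has no negatives; skipped")
                continue
            anchors.append(augment_view(seg, cfg, rng))
            positives.append(augment_view(seg, cfg, rng))
            if n_negatives is not None and len(negs) > n_negatives:
                idx = rng.choice(len(negs), size=n_negatives, replace=False)
                negs = [negs[int(j)] for j in idx]
            negatives.append(negs)

    return ContrastiveBatch(anchors=anchors, positives=positives,
                            negatives=negatives, pair_mode=mode)
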