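"""Shallow feature encoders and analytic complexity accounting.

Two encoders share one contract (a ``(N, C, T)`` batch in, a token sequence
``(N, n_tokens, d)`` out):

* ``DscSfe`` — the depthwise-separable encoder: per-electrode temporal
  filters (m each) → mean pool (factor P along time) → pointwise mixing of
  the m maps to F → depthwise spatial kernel spanning all C electrodes →
  pointwise expansion F → e·F → patch-embedding tokenizer.
* ``BaselineSfe`` — the conventional dense-convolution encoder: temporal
  conv (1×k_t, 1→F) → spatial conv (C×1, F→e·F) → max pool (factor P) →
  the same tokenizer.

Every convolution is bias-free (each is followed by batch normalization,
which makes a conv bias redundant) and the encoder BatchNorms carry no
affine pair for the same reason.  ``count_params`` / ``count_macs`` work on
declarative layer lists so the complexity comparison is analytic and does
not require instantiating weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (Tensor, BatchNorm1d, Conv1d, Linear, Module, avg_pool1d,
                 max_pool1d)


@dataclass
class EncoderConfig:
    n_channels: int = 32          # C
    window_samples: int = 512     # T
    temporal_kernel: int = 45     # k_t
    depth_multiplier: int = 2     # m
    n_filters: int = 64           # F
    spatial_kernel: int | None = None   # k_s; defaults to C (spans all electrodes)
    pool_factor: int = 4          # P
    patch_len: int = 8            # p
    embed_dim: int = 64           # d
    out_expansion: int = 2        # final pointwise expands F -> e*F

    def __post_init__(self):
        if self.spatial_kernel is None:
            self.spatial_kernel = self.n_channels
        if self.spatial_kernel != self.n_channels:
            raise ValueError("spatial kernel must span all electrodes")
        if min(self.n_channels, self.temporal_kernel, self.depth_multiplier,
               self.n_filters, self.pool_factor, self.patch_len,
               self.embed_dim, self.out_expansion) < 1:
            raise ValueError("all encoder counts must be >= 1")
        if self.window_samples % self.pool_factor:
            raise ValueError("window_samples must be divisible by pool_factor")
        if self.pooled_len % self.patch_len:
            raise ValueError("pooled length must be divisible by patch_len")

    @property
    def pooled_len(self) -> int:
        return self.window_samples // self.pool_factor

    @property
    def n_tokens(self) -> int:
        return self.pooled_len // self.patch_len

    @property
    def out_filters(self) -> int:
        return self.n_filters * self.out_expansion

    @property
    def hop_ms(self) -> float:
        """Milliseconds of raw signal represented per token (4 s window)."""
        return 1000.0 * self.window_samples / self.n_tokens / 128.0


def reference_config() -> EncoderConfig:
    """The fixed configuration used for the complexity comparison
    (32 electrodes, 4 s @ 128 Hz)."""
    return EncoderConfig()


class _PatchEmbed(Module):
    """Non-overlapping length-p patches, linearly mapped to the token dim."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.p = cfg.patch_len
        self.proj = Linear(cfg.out_filters * cfg.patch_len, cfg.embed_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        n, f, length = x.shape
        tok = length // self.p
        x = x.reshape(n, f, tok, self.p).transpose(0, 2, 1, 3)
        return self.proj(x.reshape(n, tok, f * self.p))


class DscSfe(Module):
    #: test mode: skip BN and ELU so the map is linear (up to biases)
    linear_mode = False

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c, m, f = cfg.n_channels, cfg.depth_multiplier, cfg.n_filters
        self.dw_temporal = Conv1d(c, c * m, cfg.temporal_kernel, rng,
                                  groups=c, bias=False, padding="same")
        self.bn1 = BatchNorm1d(c * m, affine=False)
        self.pw_mix = Conv1d(m, f, 1, rng, bias=False, padding="valid")
        self.bn2 = BatchNorm1d(f, affine=False)
        # depthwise spatial stage: one weight per (map, electrode)
        bound = float(np.sqrt(1.0 / c))
        self.spatial_weight = Tensor(
            rng.uniform(-bound, bound, size=(c, f)).astype(np.float32),
            requires_grad=True)
        self.bn3 = BatchNorm1d(f, affine=False)
        self.pw_out = Conv1d(f, cfg.out_filters, 1, rng, bias=False,
                             padding="valid")
        self.bn4 = BatchNorm1d(cfg.out_filters, affine=False)
        self.tokenizer = _PatchEmbed(cfg, rng)

    def temporal_response(self, x: Tensor) -> Tensor:
        """Raw depthwise temporal stage output (for filter-tap oracles)."""
        return self.dw_temporal(x)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        n = x.shape[0]
        c, m, f = cfg.n_channels, cfg.depth_multiplier, cfg.n_filters
        act = (lambda t: t) if self.linear_mode else (lambda t: t.elu())
        norm = ((lambda bn, t: t) if self.linear_mode
                else (lambda bn, t: bn(t)))
        h = act(norm(self.bn1, self.dw_temporal(x)))     # (N, C*m, T)
        h = avg_pool1d(h, cfg.pool_factor)               # (N, C*m, T/P)
        tp = h.shape[-1]
        h = h.reshape(n * c, m, tp)
        h = self.pw_mix(h)                               # (N*C, F, T/P)
        h = act(norm(self.bn2, h))
        h = h.reshape(n, c, f, tp)
        # depthwise spatial: kernel over all electrodes, one per map
        h = (h * self.spatial_weight.reshape(1, c, f, 1)).sum(axis=1)
        h = act(norm(self.bn3, h))                       # (N, F, T/P)
        h = act(norm(self.bn4, self.pw_out(h)))          # (N, e*F, T/P)
        return self.tokenizer(h)


class BaselineSfe(Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c, f = cfg.n_channels, cfg.n_filters
        self.temporal = Conv1d(1, f, cfg.temporal_kernel, rng, bias=False,
                               padding="same")
        self.bn1 = BatchNorm1d(f, affine=False)
        self.spatial = Linear(c * f, cfg.out_filters, rng, bias=False)
        self.bn2 = BatchNorm1d(cfg.out_filters, affine=False)
        self.tokenizer = _PatchEmbed(cfg, rng)

    def temporal_response(self, x: Tensor) -> Tensor:
        n, c, t = x.shape
        return self.temporal(x.reshape(n * c, 1, t))

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        n, c, t = x.shape
        f = cfg.n_filters
        h = self.temporal(x.reshape(n * c, 1, t))        # (N*C, F, T)
        h = self.bn1(h).elu().reshape(n, c, f, t)
        h = h.transpose(0, 3, 1, 2).reshape(n, t, c * f)
        h = self.spatial(h)                              # (N, T, e*F)
        h = h.transpose(0, 2, 1)                         # (N, e*F, T)
        h = self.bn2(h).elu()
        h = max_pool1d(h, cfg.pool_factor, cfg.pool_factor)
        return self.tokenizer(h)


def make_encoder(kind: str, cfg: EncoderConfig, rng: np.random.Generator):
    if kind == "dsc":
        return DscSfe(cfg, rng)
    if kind == "baseline":
        return BaselineSfe(cfg, rng)
    raise ValueError(f"unknown encoder kind {kind!r}")


def bandpass_filter_init(encoder: "DscSfe | BaselineSfe", fs: float,
                         rng: np.random.Generator,
                         low_hz: float = 4.0, high_hz: float = 30.0,
                         centers: tuple[float, ...] | None = None) -> None:
    """Initialize the temporal filters as a windowed-cosine band-pass bank.

    Random white-noise filters start with flat spectra, so every power
    feature downstream is band-unselective until training discovers
    oscillatory structure; seeding the temporal stage with narrow-band atoms
    (random phase, unit norm) is the EEG-specific analogue of wavelet
    initialization and markedly shortens training on band-power tasks.
    For the DSC encoder the m filters of each electrode cycle through
    ``centers`` (default: one per canonical band) with ±10 % jitter; the
    baseline encoder's shared bank draws uniformly in [low_hz, high_hz].
    """
    w = (encoder.dw_temporal.weight if isinstance(encoder, DscSfe)
         else encoder.temporal.weight)
    cout, _, k = w.data.shape
    t = np.arange(k) - (k - 1) / 2
    win = np.hamming(k)
    if centers is None:
        centers = (6.0, 10.5, 16.0, 24.0)      # theta, alpha, low/high beta
    m = encoder.cfg.depth_multiplier if isinstance(encoder, DscSfe) else None
    bank = np.zeros((cout, 1, k), dtype=np.float32)
    for i in range(cout):
        if m is not None:
            f = centers[(i % m) % len(centers)] * rng.uniform(0.9, 1.1)
        else:
            f = rng.uniform(low_hz, high_hz)
        f = min(f, 0.45 * fs)
        phase = rng.uniform(0, 2 * np.pi)
        h = np.cos(2 * np.pi * f * t / fs + phase) * win
        bank[i, 0] = h / np.linalg.norm(h)
    w.data = bank


# ---------------------------------------------------------------------------
# analytic complexity accounting
# ---------------------------------------------------------------------------

def dsc_sfe_layers(cfg: EncoderConfig) -> list[dict]:
    """Declarative layer list for the DSC encoder's convolutional stack."""
    c, m, f = cfg.n_channels, cfg.depth_multiplier, cfg.n_filters
    tp = cfg.pooled_len
    return [
        {"type": "conv", "depth_in": c, "depth_out": c * m,
         "k": cfg.temporal_kernel, "groups": c, "bias": False,
         "positions": cfg.window_samples},
        {"type": "bn", "features": c * m, "affine": False},
        {"type": "pool", "positions": cfg.window_samples},
        {"type": "conv", "depth_in": m, "depth_out": f, "k": 1, "groups": 1,
         "bias": False, "positions": c * tp},
        {"type": "bn", "features": f, "affine": False},
        {"type": "conv", "depth_in": c * f, "depth_out": f, "k": 1,
         "groups": f, "bias": False, "positions": tp},   # depthwise spatial
        {"type": "bn", "features": f, "affine": False},
        {"type": "conv", "depth_in": f, "depth_out": cfg.out_filters, "k": 1,
         "groups": 1, "bias": False, "positions": tp},
        {"type": "bn", "features": cfg.out_filters, "affine": False},
    ]


def baseline_sfe_layers(cfg: EncoderConfig) -> list[dict]:
    """Declarative layer list for the dense-convolution encoder."""
    c, f = cfg.n_channels, cfg.n_filters
    return [
        {"type": "conv", "depth_in": 1, "depth_out": f,
         "k": cfg.temporal_kernel, "groups": 1, "bias": False,
         "positions": c * cfg.window_samples},
        {"type": "bn", "features": f, "affine": False},
        {"type": "conv", "depth_in": f, "depth_out": cfg.out_filters,
         "k": cfg.spatial_kernel, "groups": 1, "bias": False,
         "positions": cfg.window_samples},               # 'valid' over electrodes
        {"type": "bn", "features": cfg.out_filters, "affine": False},
        {"type": "pool", "positions": cfg.window_samples},
    ]


def count_params(layers: list[dict]) -> int:
    total = 0
    for lay in layers:
        if lay["type"] == "conv":
            total += (lay["depth_in"] // lay["groups"]) * lay["depth_out"] * lay["k"]
            if lay.get("bias", True):
                total += lay["depth_out"]
        elif lay["type"] == "bn":
            total += 2 * lay["features"] if lay.get("affine", True) else 0
        elif lay["type"] == "pool":
            pass
        else:
            raise ValueError(f"unknown layer type {lay['type']!r}")
    return total


def count_macs(layers: list[dict]) -> int:
    """Multiply-accumulates for one forward pass: per-output-position
    multiplies × output positions, summed over conv layers."""
    total = 0
    for lay in layers:
        if lay["type"] == "conv":
            per_pos = (lay["depth_in"] // lay["groups"]) * lay["k"]
            total += per_pos * lay["depth_out"] * lay["positions"]
        elif lay["type"] in ("bn", "pool"):
            pass
        else:
            raise ValueError(f"unknown layer type {lay['type']!r}")
    return total


def complexity_report(cfg: EncoderConfig | None = None) -> dict:
    """Parameter and MAC comparison between the two encoders."""
    cfg = cfg or reference_config()
    pb = count_params(baseline_sfe_layers(cfg))
    pd = count_params(dsc_sfe_layers(cfg))
    mb = count_macs(baseline_sfe_layers(cfg))
    md = count_macs(dsc_sfe_layers(cfg))
    return {
        "baseline_params": pb, "dsc_params": pd,
        "param_ratio": pb / pd,
        "baseline_macs": mb, "dsc_macs": md,
        "mac_ratio": mb / md,
    }


# attention-core MAC models (used for the linear-vs-quadratic scaling check
# and the per-sample GFLOPs report)

def mgla_core_macs(n_tokens: int, dim: int, scale_windows=(1, 2, 4),
                   head_dim: int = 16) -> int:
    """Linear-attention core: per scale and head, φ(K)ᵀV and Q·(KᵀV)
    (block-diagonal over heads, so d_k not d per block) plus gating."""
    total = 0
    for w in scale_windows:
        ns = max(n_tokens // w, 1)
        total += 2 * ns * dim * min(head_dim, dim) + ns * dim
    return total


def msa_core_macs(n_tokens: int, dim: int) -> int:
    """Softmax-attention core: QKᵀ scores plus A·V (quadratic in tokens)."""
    return 2 * n_tokens * n_tokens * dim
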