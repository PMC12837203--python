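"""Attentive dense information purification.

Applied to the medium and fine branch maps of every hierarchical layer:
a log-power transform (square → centred moving average along the token
axis → log), single-head scaled dot-product self-attention over the power
map, a per-feature gated residual blending attended and raw power features,
and a learnable weighted sum fusing the refined medium and fine maps.

The moving-average window keeps the token axis (a global temporal mean
would collapse it and starve the attention of a sequence); window width is
configurable, and width = full length recovers the plain global-mean
power vector used by the non-attentive ablation.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .nn import (Tensor, Linear, Module, as_tensor, avg_pool1d, concat,
                 parameter, softmax, upsample_nearest)


@dataclass
class ADIPConfig:
    power_window: int = 8      # tokens
    eps: float = 1e-8
    gate_init: float = 0.0
    mode: str = "adip"         # 'adip' or 'dip' (global mean, no attention)


def log_power(x: Tensor | np.ndarray, w: int, eps: float = 1e-8) -> Tensor:
    """log(centred moving average of x² + eps) along the token axis.

    Input (N, n, d); edges are replicated so a constant input maps to a
    constant output.  ``w`` is clamped to the sequence length.
    """
    x = as_tensor(x)
    if w < 1:
        raise ValueError("power window must be >= 1")
    n_tok = x.shape[1]
    if w > n_tok:
        warnings.warn(f"power window {w} > sequence {n_tok}; clamped")
        w = n_tok
    sq = x * x
    if w == 1:
        return (sq + eps).log()
    left = (w - 1) // 2
    right = w - 1 - left
    parts = []
    if left:
        parts.append(upsample_nearest(sq[:, 0:1, :], left, axis=1))
    parts.append(sq)
    if right:
        parts.append(upsample_nearest(sq[:, -1:, :], right, axis=1))
    padded = concat(parts, axis=1).transpose(0, 2, 1)
    avg = avg_pool1d(padded, w, 1).transpose(0, 2, 1)
    return (avg + eps).log()


class ADIPBlock(Module):
    """Purify one token map: log-power → self-attention → gated residual."""

    def __init__(self, dim: int, cfg: ADIPConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.dim = dim
        if cfg.mode == "adip":
            self.wq = Linear(dim, dim, rng, bias=False)
            self.wk = Linear(dim, dim, rng, bias=False)
            self.wv = Linear(dim, dim, rng, bias=False)
            self.gate = parameter(np.full(dim, cfg.gate_init))
        self.last_attention: np.ndarray | None = None

    def attend(self, f_power: Tensor) -> Tensor:
        if not np.isfinite(f_power.data).all():
            raise ValueError("non-finite values entering attention")
        q, k, v = self.wq(f_power), self.wk(f_power), self.wv(f_power)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.dim))
        attn = softmax(scores, axis=-1)
        self.last_attention = attn.data
        return attn @ v

    def forward(self, x: Tensor) -> Tensor:
        w = self.cfg.power_window if self.cfg.mode == "adip" else x.shape[1]
        w = min(w, x.shape[1])
        f_power = log_power(x, w, self.cfg.eps)
        if self.cfg.mode == "dip":
            return f_power                      # global-mean power, no attention
        f_attn = self.attend(f_power)
        return gated_residual(f_attn, f_power, self.gate)


def gated_residual(f_attn: Tensor, f_power: Tensor, gate: Tensor) -> Tensor:
    """σ(G)⊙F_attn + (1−σ(G))⊙F_power — a per-feature convex combination."""
    f_attn, f_power, gate = map(as_tensor, (f_attn, f_power, gate))
    if f_attn.shape != f_power.shape:
        raise ValueError("operand shapes must match")
    g = gate.sigmoid()
    return f_attn * g + f_power * (1.0 - g)


class LayerFusion(Module):
    """Learnable weighted sum α·medium + β·fine (both initialized to 1)."""

    def __init__(self):
        super().__init__()
        self.alpha = parameter(np.array(1.0))
        self.beta = parameter(np.array(1.0))

    def forward(self, f_medium: Tensor, f_fine: Tensor) -> Tensor:
        f_medium, f_fine = as_tensor(f_medium), as_tensor(f_fine)
        if f_medium.shape != f_fine.shape:
            raise ValueError("fusion operands must share a shape")
        return f_medium * self.alpha + f_fine * self.beta


class ADIPStage(Module):
    """Per-layer purification: separate blocks for medium and fine maps,
    plus the layer's fusion weights."""

    def __init__(self, dim: int, cfg: ADIPConfig, rng: np.random.Generator):
        super().__init__()
        self.medium = ADIPBlock(dim, cfg, rng)
        self.fine = ADIPBlock(dim, cfg, rng)
        self.fusion = LayerFusion()

    def forward(self, f_mg: Tensor | None, f_fg: Tensor) -> Tensor:
        fine_ref = self.fine(f_fg)
        if f_mg is None:
            return fine_ref
        med_ref = self.medium(f_mg)
        return self.fusion(med_ref, fine_ref)
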