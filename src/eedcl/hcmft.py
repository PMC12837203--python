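"""Hierarchical coarse/medium/fine transformer layers.

Each layer runs three parallel branches over the token sequence and halves
the token count:

* coarse (CGB): multiscale gated linear attention (MG-LA), linear
  projection, max-pooled residual, layer norm, feed-forward;
* medium (MGB): kernel-7 temporal convolution, average pool (stride 2);
* fine (FGB): kernel-3 temporal convolution, stride-1 max pool followed by
  a stride-2 subsample.

The branch outputs share one shape and are summed to form the next layer's
input; the medium and fine maps are also handed to the purification module.

MG-LA pools queries/keys/values over windows of ``scale_windows[s]`` tokens,
computes the linearized product φ(Q)(φ(K)ᵀV) right-to-left (cost linear in
sequence length), upsamples back to token resolution, and combines scales
through per-scale sigmoid gates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (Tensor, BatchNorm1d, Conv1d, Dropout, FeedForward, LayerNorm,
                 Linear, Module, MultiHeadSelfAttention, as_tensor, avg_pool1d,
                 max_pool1d, parameter, subsample, upsample_nearest)


@dataclass
class MGLAConfig:
    n_scales: int = 3
    scale_windows: tuple[int, ...] = (1, 2, 4)
    head_dim: int = 16
    phi: str = "elu1"                 # 'elu1' (ELU(x)+1) or 'identity'
    gate_init: float = 0.0

    def __post_init__(self):
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        self.scale_windows = tuple(self.scale_windows[: self.n_scales])
        if list(self.scale_windows) != sorted(set(self.scale_windows)):
            raise ValueError("scale_windows must be strictly increasing")


def _phi(x: Tensor, kind: str) -> Tensor:
    if kind == "elu1":
        return x.elu() + 1.0
    if kind == "identity":
        return x
    raise ValueError(f"unknown linearization {kind!r}")


def _pool_tokens(x: Tensor, k: int, stride: int, kind: str = "avg",
                 same: bool = False) -> Tensor:
    """Pool along the token axis of a (N, n, d) tensor."""
    xt = x.transpose(0, 2, 1)
    if kind == "avg":
        xt = avg_pool1d(xt, k, stride)
    else:
        xt = max_pool1d(xt, k, stride, same=same)
    return xt.transpose(0, 2, 1)


def mg_la(q: Tensor, k: Tensor, v: Tensor, gates: Tensor,
          cfg: MGLAConfig) -> Tensor:
    """Multiscale gated linear attention on (N, n, d) query/key/value maps.

    For each scale: average-pool Q, K, V over windows of ``scale_windows[s]``
    tokens, apply the linearization φ, associate right-to-left
    (φ(Q)·(φ(K)ᵀV)), upsample back, and weight by σ(gate_s) per feature.
    Heads are folded into the feature dim: the linearized product runs
    block-diagonally over ``d // head_dim`` heads, which keeps the cost at
    O(n · d · d_k) per scale rather than O(n · d²).
    """
    q, k, v, gates = map(as_tensor, (q, k, v, gates))
    if q.shape != k.shape or k.shape != v.shape:
        raise ValueError("Q, K, V must share a shape")
    batch, n_tok, dim = q.shape
    heads = max(1, dim // cfg.head_dim) if dim % cfg.head_dim == 0 else 1
    dk = dim // heads

    def split(z: Tensor) -> Tensor:
        return z.reshape(batch, -1, heads, dk).transpose(0, 2, 1, 3)

    out = None
    for s, win in enumerate(cfg.scale_windows):
        win = min(win, n_tok)
        if n_tok % win:
            raise ValueError(f"token count {n_tok} not divisible by scale {win}")
        if win > 1:
            qs = _pool_tokens(q, win, win)
            ks = _pool_tokens(k, win, win)
            vs = _pool_tokens(v, win, win)
        else:
            qs, ks, vs = q, k, v
        qh, kh, vh = split(qs), split(ks), split(vs)       # (N, h, n_s, dk)
        kv = _phi(kh, cfg.phi).swapaxes(-1, -2) @ vh       # (N, h, dk, dk)
        ys = _phi(qh, cfg.phi) @ kv                        # (N, h, n_s, dk)
        ys = ys.transpose(0, 2, 1, 3).reshape(batch, -1, dim)
        if win > 1:
            ys = upsample_nearest(ys, win, axis=1)
        gated = ys * gates[s].sigmoid()
        out = gated if out is None else out + gated
    return out


class CoarseBranch(Module):
    """MG-LA → linear projection → pooled residual → LN → FFN; halves tokens."""

    def __init__(self, dim: int, cfg: MGLAConfig, rng: np.random.Generator,
                 attention: str = "mgla"):
        super().__init__()
        self.cfg = cfg
        self.attention = attention
        if attention == "mgla":
            self.wq = Linear(dim, dim, rng, bias=False)
            self.wk = Linear(dim, dim, rng, bias=False)
            self.wv = Linear(dim, dim, rng, bias=False)
            self.gates = parameter(
                np.full((cfg.n_scales, dim), cfg.gate_init))
        elif attention == "msa":
            self.msa = MultiHeadSelfAttention(dim, max(1, dim // cfg.head_dim),
                                              rng)
        else:
            raise ValueError(f"unknown attention {attention!r}")
        self.proj = Linear(dim, dim, rng)
        self.ln = LayerNorm(dim)
        self.ffn: Module | None = FeedForward(dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] % 2:
            raise ValueError("token count must be even")
        if self.attention == "mgla":
            a = mg_la(self.wq(x), self.wk(x), self.wv(x), self.gates, self.cfg)
        else:
            a = self.msa(x)
        a = _pool_tokens(self.proj(a), 2, 2, kind="max")
        r = _pool_tokens(x, 2, 2, kind="max")
        h = self.ln(a + r)
        return self.ffn(h) if self.ffn is not None else h


class _ConvBranch(Module):
    def __init__(self, dim: int, kernel: int, p_drop: float,
                 rng: np.random.Generator):
        super().__init__()
        self.drop = Dropout(p_drop, rng)
        self.conv = Conv1d(dim, dim, kernel, rng, padding="same")
        self.bn = BatchNorm1d(dim)

    def _stem(self, x: Tensor) -> Tensor:
        h = self.drop(x).transpose(0, 2, 1)       # (N, d, n)
        return self.bn(self.conv(h)).elu()


class FineBranch(_ConvBranch):
    """Kernel-3 conv; stride-1 max pool then stride-2 subsample."""

    KERNEL = 3

    def __init__(self, dim: int, rng: np.random.Generator, p_drop: float = 0.1):
        super().__init__(dim, self.KERNEL, p_drop, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self._stem(x)
        h = max_pool1d(h, 2, 1, same=True)
        h = subsample(h, 2, axis=-1)
        return h.transpose(0, 2, 1)


class MediumBranch(_ConvBranch):
    """Kernel-7 conv; average pool kernel 2 stride 2."""

    KERNEL = 7

    def __init__(self, dim: int, rng: np.random.Generator, p_drop: float = 0.25):
        super().__init__(dim, self.KERNEL, p_drop, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self._stem(x)
        h = avg_pool1d(h, 2, 2)
        return h.transpose(0, 2, 1)


class HCTLayer(Module):
    """One hierarchical layer; returns (next tokens, medium map, fine map)."""

    def __init__(self, dim: int, mgla_cfg: MGLAConfig, rng: np.random.Generator,
                 attention: str = "mgla", use_medium: bool = True):
        super().__init__()
        self.cgb = CoarseBranch(dim, mgla_cfg, rng, attention)
        self.mgb = MediumBranch(dim, rng) if use_medium else None
        self.fgb = FineBranch(dim, rng)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor | None, Tensor]:
        if x.shape[1] % 2:
            raise ValueError("token count must be divisible by 2")
        f_cg = self.cgb(x)
        f_fg = self.fgb(x)
        f_mg = self.mgb(x) if self.mgb is not None else None
        if f_fg.shape != f_cg.shape:
            raise RuntimeError("branch shape contract violated")
        out = f_cg + f_fg
        if f_mg is not None:
            if f_mg.shape != f_cg.shape:
                raise RuntimeError("branch shape contract violated")
            out = out + f_mg
        return out, f_mg, f_fg
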