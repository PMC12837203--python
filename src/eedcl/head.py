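"""Feature combination, final transformer encoder, classifier, and the
contrastive projection head."""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .nn import (Tensor, Dropout, Linear, Module, TransformerEncoderLayer,
                 as_tensor, avg_pool1d, concat, softmax)


@dataclass
class HeadConfig:
    embed_dim: int = 64
    n_encoder_layers: int = 2      # 0 disables the transformer encoder
    n_heads: int = 4
    n_classes: int = 2
    proj_dim: int = 128            # contrastive embedding dimension
    dropout: float = 0.5


def combine(f_integ: Tensor, fusions: list[Tensor]) -> Tensor:
    """Concatenate the final integrated map with each layer's fusion map
    along the token axis, after average-pooling every fusion map down to
    the final token count.  Order: integrated, then layers first → last."""
    f_integ = as_tensor(f_integ)
    n_final = f_integ.shape[1]
    if not fusions:
        warnings.warn("no fusion maps; using the integrated map alone")
        return f_integ
    pooled = [f_integ]
    for f in fusions:
        f = as_tensor(f)
        factor = f.shape[1] // n_final
        if factor > 1:
            f = avg_pool1d(f.transpose(0, 2, 1), factor).transpose(0, 2, 1)
        pooled.append(f)
    return concat(pooled, axis=1)


class Head(Module):
    """Transformer encoder (optional) + MLP classifier + projection head."""

    def __init__(self, cfg: HeadConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d = cfg.embed_dim
        self.encoder_layers = [
            TransformerEncoderLayer(d, cfg.n_heads, rng)
            for _ in range(cfg.n_encoder_layers)
        ]
        self.cls_fc1 = Linear(d, 2 * d, rng)
        self.cls_drop = Dropout(cfg.dropout, rng)
        self.cls_fc2 = Linear(2 * d, cfg.n_classes, rng)
        self.proj_fc1 = Linear(d, d, rng)
        self.proj_fc2 = Linear(d, cfg.proj_dim, rng)

    def encode(self, f_concat: Tensor) -> Tensor:
        """Transformer encoder over the combined tokens, mean-pooled to H."""
        h = as_tensor(f_concat)
        for layer in self.encoder_layers:
            h = layer(h)
        return h.mean(axis=1)

    def logits(self, h: Tensor) -> Tensor:
        return self.cls_fc2(self.cls_drop(self.cls_fc1(h).elu()))

    def classify(self, h: Tensor) -> Tensor:
        """Class probabilities (softmax over the MLP logits)."""
        return softmax(self.logits(h), axis=-1)

    def project(self, f_concat: Tensor, eps: float = 1e-12) -> Tensor:
        """Mean-pool tokens → 2-layer MLP → L2-normalized embedding."""
        z = as_tensor(f_concat).mean(axis=1)
        z = self.proj_fc2(self.proj_fc1(z).elu())
        norm = ((z * z).sum(axis=-1, keepdims=True) + eps) ** 0.5
        return z / norm
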