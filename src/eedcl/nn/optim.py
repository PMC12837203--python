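"""Optimizers (AdamW with decoupled weight decay)."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class AdamW:
    """AdamW: Adam moments on gradients, weight decay applied to the weights
    directly (decoupled), as used for all training in this package."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.param_groups = [{"params": list(params), "lr": lr,
                              "weight_decay": weight_decay}]
        self.betas = betas
        self.eps = eps
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}
        self._t = 0

    def add_group(self, params: list[Tensor], lr: float,
                  weight_decay: float = 0.01) -> None:
        self.param_groups.append({"params": list(params), "lr": lr,
                                  "weight_decay": weight_decay})

    def zero_grad(self) -> None:
        for group in self.param_groups:
            for p in group["params"]:
                p.zero_grad()

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for group in self.param_groups:
            lr, wd = group["lr"], group["weight_decay"]
            for p in group["params"]:
                if p.grad is None:
                    continue
                g = p.grad
                key = id(p)
                m = self._m.setdefault(key, np.zeros_like(p.data))
                v = self._v.setdefault(key, np.zeros_like(p.data))
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p.data -= lr * wd * p.data
                p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
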