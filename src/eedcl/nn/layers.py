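"""Neural-network modules on top of the autograd engine."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor, conv1d, normalize, softmax


def parameter(data: np.ndarray) -> Tensor:
    t = Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)
    return t


class Module:
    """Minimal module base: parameter discovery, train/eval mode, state dict."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- serialization: parameters plus non-trainable buffers (BN statistics)
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, p in self.named_parameters(prefix):
            out[name] = p.data.copy()
        for m_name, m in self._named_modules(prefix):
            for b in getattr(m, "_buffers", ()):
                out[f"{m_name}{b}"] = np.asarray(getattr(m, b)).copy()
        return out

    def _named_modules(self, prefix: str = ""):
        yield prefix, self
        for k, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v._named_modules(f"{prefix}{k}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._named_modules(f"{prefix}{k}.{i}.")

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.array(state[name], dtype=p.data.dtype)
        for m_name, m in self._named_modules():
            for b in getattr(m, "_buffers", ()):
                key = f"{m_name}{b}"
                if key in state:
                    setattr(m, b, np.array(state[key]))


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        bound = float(np.sqrt(6.0 / (n_in + n_out)))
        self.weight = parameter(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.bias = parameter(np.zeros(n_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv1d(Module):
    """Grouped stride-1 cross-correlation with 'same' or 'valid' padding."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 groups: int = 1, bias: bool = True, padding: str = "same"):
        super().__init__()
        if c_in % groups or c_out % groups:
            raise ValueError("channel counts must be divisible by groups")
        fan_in = (c_in // groups) * k
        bound = float(np.sqrt(1.0 / fan_in))
        self.weight = parameter(
            rng.uniform(-bound, bound, size=(c_out, c_in // groups, k)))
        self.bias = parameter(np.zeros(c_out)) if bias else None
        self.groups = groups
        if padding == "same":
            if k % 2 == 0:
                raise ValueError("'same' padding requires an odd kernel")
            self.pad = (k - 1) // 2
        elif padding == "valid":
            self.pad = 0
        else:
            raise ValueError(f"unknown padding {padding!r}")

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, groups=self.groups, pad=self.pad)


class BatchNorm1d(Module):
    """Batch normalization over (N, C) or (N, C, L) with running statistics."""

    _buffers = ("running_mean", "running_var")

    def __init__(self, n_features: int, eps: float = 1e-5, momentum: float = 0.1,
                 affine: bool = True):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(n_features, dtype=np.float32)
        self.running_var = np.ones(n_features, dtype=np.float32)
        self.gamma = parameter(np.ones(n_features)) if affine else None
        self.beta = parameter(np.zeros(n_features)) if affine else None

    def forward(self, x: Tensor) -> Tensor:
        axes = (0,) if x.ndim == 2 else (0, 2)
        view = (1, -1) if x.ndim == 2 else (1, -1, 1)
        if self.training:
            y, mu, var = normalize(x, axes, self.eps)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.reshape(-1)
        else:
            mu = Tensor(self.running_mean.reshape(view))
            var = Tensor(self.running_var.reshape(view))
            y = (x - mu) * (var + self.eps) ** -0.5
        if self.gamma is not None:
            y = y * self.gamma.reshape(view) + self.beta.reshape(view)
        return y


class LayerNorm(Module):
    """Per-token normalization over the last (feature) axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = parameter(np.ones(dim))
        self.beta = parameter(np.zeros(dim))

    def normalize(self, x: Tensor) -> Tensor:
        y, _, _ = normalize(x, -1, self.eps)
        return y

    def forward(self, x: Tensor) -> Tensor:
        return self.normalize(x) * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask.astype(x.data.dtype))


class ELU(Module):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x: Tensor) -> Tensor:
        return x.elu(self.alpha)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class FeedForward(Module):
    """Two-layer position-wise MLP with ELU, hidden width ``mult * dim``."""

    def __init__(self, dim: int, rng: np.random.Generator, mult: int = 2):
        super().__init__()
        self.fc1 = Linear(dim, mult * dim, rng)
        self.fc2 = Linear(mult * dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).elu())


class MultiHeadSelfAttention(Module):
    """Standard scaled-dot-product MSA over (N, n_tokens, d)."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.wq = Linear(dim, dim, rng, bias=False)
        self.wk = Linear(dim, dim, rng, bias=False)
        self.wv = Linear(dim, dim, rng, bias=False)
        self.wo = Linear(dim, dim, rng, bias=False)
        self.last_attention: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        n, t, d = x.shape
        h, hd = self.n_heads, self.head_dim

        def split(z: Tensor) -> Tensor:
            return z.reshape(n, t, h, hd).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(hd))
        attn = softmax(scores, axis=-1)
        self.last_attention = attn.data
        y = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
        return self.wo(y)


class TransformerEncoderLayer(Module):
    """Pre-LN transformer block (MSA + FFN, residual connections)."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.ffn = FeedForward(dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.ffn(self.ln2(x))
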