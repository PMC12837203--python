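"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine: each :class:`Tensor` wraps an ``ndarray`` and
remembers how it was produced, so :meth:`Tensor.backward` can walk the graph
in reverse topological order and accumulate gradients.  Only the operations
needed by the EEG model family in this package are provided (dense and
grouped 1-D convolution, pooling, elementwise nonlinearities, reductions,
matmul, concatenation, slicing).  Stride-1 convolution gradients reuse the
forward correlation kernel with a flipped filter bank, so no scatter loops
appear on the hot path.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_shared")

    def __init__(self, data, requires_grad: bool = False, _parents: tuple = (),
                 _backward=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward
        self._grad_shared = False

    # ------------------------------------------------------------------ basic
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        # first accumulation keeps a reference (flagged shared, never mutated
        # in place); later accumulations allocate once, then add in place
        if self.grad is None:
            g = np.asarray(g)
            if g.dtype != self.data.dtype:
                g = g.astype(self.data.dtype)
            if g.shape != self.data.shape:
                g = np.broadcast_to(g, self.data.shape)
            self.grad = g
            self._grad_shared = True
        elif self._grad_shared:
            self.grad = self.grad + g
            self._grad_shared = False
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs here can be a few thousand nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(-g)
        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))
        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                ga = g @ other.data.swapaxes(-1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = self.data.swapaxes(-1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))
        out._backward = bwd
        return out

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out.data)
        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = bwd
        return out

    def sqrt(self):
        return self ** 0.5

    def sigmoid(self):
        out = Tensor(_sigmoid(self.data), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out.data * (1.0 - out.data))
        out._backward = bwd
        return out

    def elu(self, alpha: float = 1.0):
        neg = self.data < 0
        y = self.data.copy()
        y[neg] = alpha * np.expm1(self.data[neg])
        out = Tensor(y, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                gx = np.array(g)            # copy: g may be a shared buffer
                gx[neg] = g[neg] * (y[neg] + alpha)
                self._accum(gx)
        out._backward = bwd
        return out

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))
        out._backward = bwd
        return out

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))
        out._backward = bwd
        return out

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, key):
        out = Tensor(self.data[key], self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full)
        out._backward = bwd
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape))
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def __repr__(self):  # pragma: no cover - debug helper
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=x.dtype if x.dtype.kind == "f" else np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])
    out._backward = bwd
    return out


def normalize(x: Tensor, axes, eps: float = 1e-5) -> tuple[Tensor, np.ndarray,
                                                           np.ndarray]:
    """Fused moment normalization: (x − μ)/√(var + eps) over ``axes``.

    Returns (normalized tensor, μ, var); μ/var are plain arrays (used for
    running statistics).  One graph node instead of the ~10 an op-by-op
    composition would create.
    """
    xd = x.data
    mu = xd.mean(axis=axes, keepdims=True)
    var = xd.var(axis=axes, keepdims=True)
    s = np.sqrt(var + eps)
    y = (xd - mu) / s
    out = Tensor(y, x.requires_grad, (x,))

    def bwd(g):
        if not x.requires_grad:
            return
        gm = g.mean(axis=axes, keepdims=True)
        gym = (g * y).mean(axis=axes, keepdims=True)
        x._accum((g - gm - y * gym) / s)
    out._backward = bwd
    return out, mu, var


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant, no grad
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def upsample_nearest(x: Tensor, factor: int, axis: int) -> Tensor:
    """Repeat each entry ``factor`` times along ``axis`` (nearest-neighbour)."""
    out = Tensor(np.repeat(x.data, factor, axis=axis), x.requires_grad, (x,))

    def bwd(g):
        if not x.requires_grad:
            return
        shp = list(g.shape)
        ax = axis % g.ndim
        shp[ax:ax + 1] = [x.shape[ax], factor]
        x._accum(g.reshape(shp).sum(axis=ax + 1))
    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# 1-D convolution (stride 1) and pooling
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, groups: int, pad: int):
    """Column matrix for stride-1 grouped correlation.

    Returns (cols, n, lout): cols is (N*Lout, Cin*k) for groups == 1, else
    (G, N*Lout, Cin_g*k).
    """
    n, cin, _ = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    win = sliding_window_view(x, k, axis=-1)              # (N, Cin, Lout, k)
    lout = win.shape[2]
    if groups == 1:
        cols = win.transpose(0, 2, 1, 3).reshape(n * lout, cin * k)
    else:
        cols = win.reshape(n, groups, cin // groups, lout, k)
        cols = cols.transpose(1, 0, 3, 2, 4).reshape(groups, n * lout,
                                                     (cin // groups) * k)
    return cols, n, lout


def _cols_matmul(cols, w: np.ndarray, groups: int, n: int,
                 lout: int) -> np.ndarray:
    cout, cin_g, k = w.shape
    if groups == 1:
        out = cols @ w.reshape(cout, cin_g * k).T
        return out.reshape(n, lout, cout).transpose(0, 2, 1)
    wg = w.reshape(groups, cout // groups, cin_g * k)
    out = cols @ wg.transpose(0, 2, 1)                    # (G, N*Lout, Og)
    out = out.reshape(groups, n, lout, cout // groups)
    return out.transpose(1, 0, 3, 2).reshape(n, cout, lout)


def _conv_fwd(x: np.ndarray, w: np.ndarray, groups: int, pad: int) -> np.ndarray:
    """Raw grouped cross-correlation, stride 1.

    x: (N, Cin, L); w: (Cout, Cin // groups, k) -> (N, Cout, L + 2*pad - k + 1)
    """
    cols, n, lout = _im2col(x, w.shape[-1], groups, pad)
    return _cols_matmul(cols, w, groups, n, lout)


def conv1d(x: Tensor, w: Tensor, bias: Tensor | None = None, *,
           groups: int = 1, pad: int = 0) -> Tensor:
    """Grouped stride-1 cross-correlation along the last axis.

    The spatial-filter convention throughout the package is cross-correlation
    (no kernel flip), matching the common deep-learning definition.
    """
    xd, wd = x.data, w.data
    cout, cin_g, k = wd.shape
    parents = (x, w) if bias is None else (x, w, bias)
    cols, n, lout = _im2col(xd, k, groups, pad)
    y = _cols_matmul(cols, wd, groups, n, lout)
    if bias is not None:
        y = y + bias.data[None, :, None]
    if not w.requires_grad:
        cols = None                      # release the column matrix early
    out = Tensor(y, any(p.requires_grad for p in parents), parents)

    def bwd(g):
        if w.requires_grad:
            # reuse the forward column matrix
            gg = g.reshape(n, groups, cout // groups, lout)
            gg = gg.transpose(1, 2, 0, 3).reshape(groups, cout // groups,
                                                  n * lout)
            if groups == 1:
                gw = gg[0] @ cols
            else:
                gw = gg @ cols                            # (G, Og, Cg*k)
            w._accum(gw.reshape(cout, cin_g, k))
        if x.requires_grad:
            # stride-1 identity: dL/dx = corr(dL/dy, w flipped & channel-swapped)
            wg = wd.reshape(groups, cout // groups, cin_g, k)
            wt = wg[:, :, :, ::-1].transpose(0, 2, 1, 3)   # (G, Cin_g, Cout_g, k)
            wt = np.ascontiguousarray(wt.reshape(cin_g * groups, cout // groups, k))
            gx_full = _conv_fwd(g, wt, groups, pad=k - 1)
            L = xd.shape[-1]
            x._accum(gx_full[:, :, pad:pad + L])
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2)))
    out._backward = bwd
    return out


def avg_pool1d(x: Tensor, k: int, stride: int | None = None) -> Tensor:
    """Average pooling along the last axis; trailing remainder is dropped."""
    stride = stride or k
    L = x.shape[-1]
    if stride == k and L % k == 0:
        shp = x.shape[:-1] + (L // k, k)
        return x.reshape(shp).mean(axis=-1)
    win = sliding_window_view(x.data, k, axis=-1)[..., ::stride, :]
    out = Tensor(win.mean(axis=-1), x.requires_grad, (x,))
    starts = np.arange(out.shape[-1]) * stride

    def bwd(g):
        if not x.requires_grad:
            return
        full = np.zeros_like(x.data)
        for j, s in enumerate(starts):
            full[..., s:s + k] += g[..., j:j + 1] / k
        x._accum(full)
    out._backward = bwd
    return out


def max_pool1d(x: Tensor, k: int, stride: int, same: bool = False) -> Tensor:
    """Max pooling along the last axis.

    ``same=True`` right-pads with -inf so the output keeps the input length
    (used by the stride-1 fine-branch pooling).
    """
    xd = x.data
    if same:
        pad = k - 1
        xd = np.concatenate(
            [xd, np.full(xd.shape[:-1] + (pad,), -np.inf, dtype=xd.dtype)], axis=-1)
    win = sliding_window_view(xd, k, axis=-1)[..., ::stride, :]
    arg = win.argmax(axis=-1)
    out = Tensor(np.take_along_axis(win, arg[..., None], axis=-1)[..., 0],
                 x.requires_grad, (x,))
    starts = np.arange(out.shape[-1]) * stride

    def bwd(g):
        if not x.requires_grad:
            return
        # C-contiguous buffer: reshape below must be a view, not a copy
        full = np.zeros(x.data.shape, dtype=x.data.dtype)
        pos = starts + arg                      # (..., Lout) absolute indices
        lead = np.indices(pos.shape[:-1])
        flat = full.reshape(-1, full.shape[-1])
        row = np.ravel_multi_index(lead, full.shape[:-1]) if full.ndim > 1 else None
        if row is None:
            np.add.at(flat[0], pos.clip(max=full.shape[-1] - 1), g)
        else:
            rows = np.broadcast_to(row[..., None], pos.shape)
            np.add.at(flat, (rows.ravel(), pos.clip(max=full.shape[-1] - 1).ravel()),
                      g.ravel())
        x._accum(full)
    out._backward = bwd
    return out


def subsample(x: Tensor, step: int, axis: int = -1) -> Tensor:
    idx = [slice(None)] * x.ndim
    idx[axis] = slice(None, None, step)
    return x[tuple(idx)]


def stop_gradient(x: Tensor) -> Tensor:
    return Tensor(x.data)


def gradcheck(fn, tensors: Iterable[Tensor], eps: float = 1e-6,
              rtol: float = 1e-4) -> float:
    """Compare analytic gradients of ``fn(*tensors).sum()`` with central
    finite differences; returns the worst relative error."""
    tensors = list(tensors)
    for t in tensors:
        t.requires_grad = True
        t.zero_grad()
    out = fn(*tensors)
    out.sum().backward()
    worst = 0.0
    for t in tensors:
        num = np.zeros_like(t.data)
        flat = t.data.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = fn(*tensors).data.sum()
            flat[i] = orig - eps
            lo = fn(*tensors).data.sum()
            flat[i] = orig
            num.reshape(-1)[i] = (hi - lo) / (2 * eps)
        denom = max(np.abs(num).max(), np.abs(t.grad).max(), 1e-8)
        worst = max(worst, float(np.abs(num - t.grad).max() / denom))
    if worst > rtol:
        raise AssertionError(f"gradcheck failed: rel err {worst:.3e} > {rtol}")
    return worst
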