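"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set needed by the models in this package:
broadcasting arithmetic, (batched) matmul, reshape/transpose/indexing,
tanh/sigmoid/GELU, fused softmax, fused layer normalization, embedding
lookup, and fused softmax cross-entropy. Gradients are accumulated on a
dynamically built tape and released after :meth:`Tensor.backward`.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "matmul",
    "softmax",
    "layer_norm",
    "embedding",
    "take",
    "concat",
    "softmax_cross_entropy",
    "no_grad",
]

_grad_enabled = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_diff = grad.ndim - len(shape)
    if ndim_diff > 0:
        grad = grad.sum(axis=tuple(range(ndim_diff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()
        self.name = name

    # -- infrastructure -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        # store by reference on first touch; later accumulations allocate a
        # fresh array so shared grad buffers are never mutated in place
        if self.grad is None:
            self.grad = g if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in seen:
                    stack.append((child, False))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
            # release the tape as we go
            node._backward = None
            node._prev = ()

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other, like=self)
        out = _make(self.data + other.data, (self, other))
        if out.requires_grad:

            def bw():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad, self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad, other.data.shape))

            out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other, like=self)
        out = _make(self.data * other.data, (self, other))
        if out.requires_grad:

            def bw():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad * other.data, self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad * self.data, other.data.shape))

            out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other, like=self))

    def __rsub__(self, other):
        return as_tensor(other, like=self) + (-self)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        return self * other.pow(-1.0)

    def pow(self, p: float):
        out = _make(self.data**p, (self,))
        if out.requires_grad:

            def bw():
                self._accumulate(out.grad * p * self.data ** (p - 1))

            out._backward = bw
        return out

    def exp(self):
        out = _make(np.exp(self.data), (self,))
        if out.requires_grad:

            def bw():
                self._accumulate(out.grad * out.data)

            out._backward = bw
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out.requires_grad:

            def bw():
                self._accumulate(out.grad / self.data)

            out._backward = bw
        return out

    def tanh(self):
        out = _make(np.tanh(self.data), (self,))
        if out.requires_grad:

            def bw():
                self._accumulate(out.grad * (1.0 - out.data**2))

            out._backward = bw
        return out

    def sigmoid(self):
        out = _make(1.0 / (1.0 + np.exp(-self.data)), (self,))
        if out.requires_grad:

            def bw():
                self._accumulate(out.grad * out.data * (1.0 - out.data))

            out._backward = bw
        return out

    def gelu(self):
        # tanh approximation (used by most transformer implementations)
        c = math.sqrt(2.0 / math.pi)
        x = self.data
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out = _make(0.5 * x * (1.0 + t), (self,))
        if out.requires_grad:

            def bw():
                dt = (1.0 - t**2) * c * (1.0 + 3 * 0.044715 * x**2)
                self._accumulate(out.grad * (0.5 * (1.0 + t) + 0.5 * x * dt))

            out._backward = bw
        return out

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        out = _make(self.data.reshape(*shape), (self,))
        if out.requires_grad:

            def bw():
                self._accumulate(out.grad.reshape(self.data.shape))

            out._backward = bw
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        out = _make(self.data.transpose(*axes), (self,))
        if out.requires_grad:
            inv = np.argsort(axes)

            def bw():
                self._accumulate(out.grad.transpose(*inv))

            out._backward = bw
        return out

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))
        if out.requires_grad:

            def bw():
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accumulate(g)

            out._backward = bw
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:

            def bw():
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape))

            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def _make(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    req = _grad_enabled and any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req)
    if req:
        out._prev = tuple(p for p in parents if p.requires_grad)
    return out


def as_tensor(x, like: Tensor | None = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    dtype = like.data.dtype if like is not None else None
    return Tensor(np.asarray(x, dtype=dtype))


# -- linear algebra -----------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = _make(np.matmul(a.data, b.data), (a, b))
    if out.requires_grad:

        def bw():
            if a.requires_grad:
                ga = np.matmul(out.grad, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), out.grad)
                b._accumulate(_unbroadcast(gb, b.data.shape))

        out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = _make(y, (x,))
    if out.requires_grad:

        def bw():
            g = out.grad
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accumulate(y * (g - dot))

        out._backward = bw
    return out


def scaled_attention(q: Tensor, k: Tensor, v: Tensor, scale: float) -> tuple[Tensor, np.ndarray]:
    """Fused softmax(q @ k^T * scale) @ v for (..., s, d) heads.

    Stores only q/k/v and the attention weights on the tape (the raw score
    matrix is released immediately), which matters for long sequences.
    Returns (output, attention weights array).
    """
    scores = np.matmul(q.data, np.swapaxes(k.data, -1, -2))
    scores *= scale
    scores -= scores.max(axis=-1, keepdims=True)
    np.exp(scores, out=scores)
    scores /= scores.sum(axis=-1, keepdims=True)
    att = scores  # row-stochastic weights; scores buffer reused
    out = _make(np.matmul(att, v.data), (q, k, v))
    if out.requires_grad:

        def bw():
            g = out.grad
            if v.requires_grad:
                v._accumulate(np.matmul(np.swapaxes(att, -1, -2), g))
            datt = np.matmul(g, np.swapaxes(v.data, -1, -2))
            datt *= att
            dscores = datt
            dscores -= att * datt.sum(axis=-1, keepdims=True)
            dscores *= scale
            if q.requires_grad:
                q._accumulate(np.matmul(dscores, k.data))
            if k.requires_grad:
                k._accumulate(np.matmul(np.swapaxes(dscores, -1, -2), q.data))

        out._backward = bw
    return out, att


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = _make(xhat * gamma.data + beta.data, (x, gamma, beta))
    if out.requires_grad:

        def bw():
            g = out.grad
            if gamma.requires_grad:
                gamma._accumulate(_unbroadcast(g * xhat, gamma.data.shape))
            if beta.requires_grad:
                beta._accumulate(_unbroadcast(g, beta.data.shape))
            if x.requires_grad:
                n = x.data.shape[-1]
                gx = g * gamma.data
                dx = inv * (
                    gx
                    - gx.mean(axis=-1, keepdims=True)
                    - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
                )
                _ = n  # dims folded into the means above
                x._accumulate(dx)

        out._backward = bw
    return out


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    ids = np.asarray(ids)
    out = _make(table.data[ids], (table,))
    if out.requires_grad:

        def bw():
            g = np.zeros_like(table.data)
            np.add.at(g, ids.reshape(-1), out.grad.reshape(-1, table.data.shape[-1]))
            table._accumulate(g)

        out._backward = bw
    return out


def take(x: Tensor, *index_arrays: np.ndarray) -> Tensor:
    """Advanced indexing x[idx0, idx1, ...] with scatter-add backward."""
    idx = tuple(np.asarray(i) for i in index_arrays)
    out = _make(x.data[idx], (x,))
    if out.requires_grad:

        def bw():
            g = np.zeros_like(x.data)
            np.add.at(g, idx, out.grad)
            x._accumulate(g)

        out._backward = bw
    return out


def concat(parts: Sequence[Tensor], axis: int = -1) -> Tensor:
    out = _make(np.concatenate([p.data for p in parts], axis=axis), tuple(parts))
    if out.requires_grad:
        sizes = [p.data.shape[axis] for p in parts]
        offsets = np.cumsum([0] + sizes)

        def bw():
            for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
                if p.requires_grad:
                    sl = [slice(None)] * out.grad.ndim
                    sl[axis] = slice(lo, hi)
                    p._accumulate(out.grad[tuple(sl)])

        out._backward = bw
    return out


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer `targets` under row-wise softmax of `logits`.

    `logits` has shape (N, V), `targets` shape (N,). Returns a scalar Tensor.
    """
    targets = np.asarray(targets)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1))
    loss_val = (lse - z[np.arange(n), targets]).mean()
    out = _make(np.asarray(loss_val, dtype=logits.data.dtype), (logits,))
    if out.requires_grad:

        def bw():
            p = np.exp(z - lse[:, None])
            p[np.arange(n), targets] -= 1.0
            logits._accumulate(out.grad * p / n)

        out._backward = bw
    return out


def parameters_of(obj: Iterable[Tensor] | dict) -> list[Tensor]:
    if isinstance(obj, dict):
        obj = obj.values()
    return [t for t in obj if isinstance(t, Tensor) and t.requires_grad]
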