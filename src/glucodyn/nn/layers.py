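"""Neural building blocks: linear/layer-norm modules, multi-head
self-attention, pre-norm transformer blocks, sinusoidal positions, and a
gated (LSTM) recurrent cell. All parameters are float32 ``Tensor`` leaves
held in flat dicts so checkpoints are a plain name -> array mapping.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, concat, layer_norm, matmul, scaled_attention, softmax

__all__ = [
    "init_linear",
    "Linear",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerBlock",
    "sinusoidal_positions",
    "LSTMCell",
    "Dropout",
]

DTYPE = np.float32


def init_linear(rng: np.random.Generator, n_in: int, n_out: int, std: float = 0.02):
    w = rng.normal(0.0, std, size=(n_in, n_out)).astype(DTYPE)
    b = np.zeros(n_out, dtype=DTYPE)
    return Tensor(w, requires_grad=True), Tensor(b, requires_grad=True)


class Linear:
    def __init__(self, rng, n_in, n_out, std=0.02, prefix=""):
        self.w, self.b = init_linear(rng, n_in, n_out, std)
        self.names = {f"{prefix}w": self.w, f"{prefix}b": self.b}

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.w) + self.b


class LayerNorm:
    def __init__(self, dim, prefix=""):
        self.gamma = Tensor(np.ones(dim, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=DTYPE), requires_grad=True)
        self.names = {f"{prefix}gamma": self.gamma, f"{prefix}beta": self.beta}

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class Dropout:
    def __init__(self, p: float):
        self.p = float(p)

    def __call__(self, x: Tensor, train: bool, rng: np.random.Generator | None):
        if not train or self.p <= 0.0:
            return x
        keep = (rng.random(x.shape) >= self.p).astype(x.data.dtype) / (1.0 - self.p)
        return x * Tensor(keep)


class MultiHeadSelfAttention:
    def __init__(self, rng, d_model: int, n_heads: int, prefix=""):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.q = Linear(rng, d_model, d_model, prefix=f"{prefix}q.")
        self.k = Linear(rng, d_model, d_model, prefix=f"{prefix}k.")
        self.v = Linear(rng, d_model, d_model, prefix=f"{prefix}v.")
        self.o = Linear(rng, d_model, d_model, prefix=f"{prefix}o.")
        self.names = {**self.q.names, **self.k.names, **self.v.names, **self.o.names}

    def __call__(self, x: Tensor, return_attention: bool = False):
        b, s, d = x.shape
        h, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:
            return t.reshape(b, s, h, dh).transpose(0, 2, 1, 3)  # (b, h, s, dh)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        ctx, att = scaled_attention(q, k, v, 1.0 / math.sqrt(dh))
        out = self.o(ctx.transpose(0, 2, 1, 3).reshape(b, s, d))
        if return_attention:
            return out, att
        return out


class TransformerBlock:
    """Pre-norm block: x + attn(LN(x)); x + GELU-MLP(LN(x))."""

    def __init__(self, rng, d_model: int, n_heads: int, d_ff: int, dropout: float, prefix=""):
        self.ln1 = LayerNorm(d_model, prefix=f"{prefix}ln1.")
        self.attn = MultiHeadSelfAttention(rng, d_model, n_heads, prefix=f"{prefix}attn.")
        self.ln2 = LayerNorm(d_model, prefix=f"{prefix}ln2.")
        self.ff1 = Linear(rng, d_model, d_ff, prefix=f"{prefix}ff1.")
        self.ff2 = Linear(rng, d_ff, d_model, prefix=f"{prefix}ff2.")
        self.drop = Dropout(dropout)
        self.names = {
            **self.ln1.names, **self.attn.names, **self.ln2.names,
            **self.ff1.names, **self.ff2.names,
        }

    def __call__(self, x, train=False, rng=None, return_attention=False):
        att_w = None
        if return_attention:
            a, att_w = self.attn(self.ln1(x), return_attention=True)
        else:
            a = self.attn(self.ln1(x))
        x = x + self.drop(a, train, rng)
        f = self.ff2(self.ff1(self.ln2(x)).gelu())
        x = x + self.drop(f, train, rng)
        if return_attention:
            return x, att_w
        return x


def sinusoidal_positions(max_positions: int, d_model: int) -> np.ndarray:
    """Standard sin/cos positional encoding matrix (max_positions, d_model)."""
    if max_positions <= 0 or d_model <= 0:
        raise ValueError("max_positions and d_model must be positive")
    pos = np.arange(max_positions, dtype=np.float64)[:, None]
    i = np.arange(d_model // 2, dtype=np.float64)[None, :]
    angles = pos / np.power(10000.0, 2 * i / d_model)
    enc = np.zeros((max_positions, d_model), dtype=np.float64)
    enc[:, 0::2] = np.sin(angles)
    enc[:, 1::2] = np.cos(angles[:, : d_model - d_model // 2])
    return enc.astype(DTYPE)


class LSTMCell:
    """Single gated recurrent cell; gate order i, f, g, o."""

    def __init__(self, rng, n_in: int, n_hidden: int, prefix=""):
        self.n_hidden = n_hidden
        scale = 1.0 / math.sqrt(n_hidden)
        self.wx = Tensor(rng.uniform(-scale, scale, (n_in, 4 * n_hidden)).astype(DTYPE),
                         requires_grad=True)
        self.wh = Tensor(rng.uniform(-scale, scale, (n_hidden, 4 * n_hidden)).astype(DTYPE),
                         requires_grad=True)
        b = np.zeros(4 * n_hidden, dtype=DTYPE)
        b[n_hidden:2 * n_hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)
        self.names = {f"{prefix}wx": self.wx, f"{prefix}wh": self.wh, f"{prefix}b": self.b}

    def __call__(self, x: Tensor, h: Tensor, c: Tensor):
        n = self.n_hidden
        z = matmul(x, self.wx) + matmul(h, self.wh) + self.b
        i = z[..., 0:n].sigmoid()
        f = z[..., n:2 * n].sigmoid()
        g = z[..., 2 * n:3 * n].tanh()
        o = z[..., 3 * n:4 * n].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new


def stack_states(states, axis=1):
    return concat([s.reshape(s.shape[0], 1, s.shape[1]) for s in states], axis=axis)
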