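"""Neural-network layers with hand-written forward and backward passes.

All sequence tensors use the layout ``(batch, time, channels)`` so that both
the convolutional backbone and the attention layers share one convention.
Every layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients into ``Param.grad``; ``backward`` returns
the gradient with respect to the layer input.  Gradients are exact (they are
checked against central finite differences in the test suite).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf

__all__ = [
    "Param", "Module", "Sequential", "Conv1d", "BatchNorm", "Linear",
    "LayerNorm", "GELU", "ReLU", "Dropout", "MultiHeadSelfAttention",
    "PositionalEncoding", "MaxAvgFuse", "softmax",
]


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=axis, keepdims=True)
    return z


class Param:
    """A trainable tensor with its gradient and bookkeeping tags.

    ``role`` drives the layer-wise learning-rate grouping (backbone /
    attention / classifier); ``decay`` marks whether AdamW weight decay
    applies (disabled for biases and normalization parameters).
    """

    __slots__ = ("name", "data", "grad", "role", "decay")

    def __init__(self, data: np.ndarray, name: str, role: str, decay: bool = True):
        self.data = np.asarray(data)
        self.grad = np.zeros_like(self.data)
        self.name = name
        self.role = role
        self.decay = decay

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: parameter registry, child traversal, train/eval mode."""

    def __init__(self) -> None:
        self._params: list[Param] = []
        self._children: list[Module] = []
        self.training = False

    def register(self, child: "Module") -> "Module":
        self._children.append(child)
        return child

    def add_param(self, data, name, role, decay=True) -> Param:
        p = Param(data, name, role, decay)
        self._params.append(p)
        return p

    def parameters(self) -> list[Param]:
        out = list(self._params)
        for c in self._children:
            out.extend(c.parameters())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def train(self, mode: bool = True) -> None:
        self.training = mode
        for c in self._children:
            c.train(mode)

    def eval(self) -> None:
        self.train(False)

    def set_rng(self, rng: np.random.Generator) -> None:
        if hasattr(self, "rng"):
            self.rng = rng
        for c in self._children:
            c.set_rng(rng)

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # state round-trip (checkpointing / best-epoch restore)
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.data.copy() for p in self.parameters()}
        for c in self._iter_modules():
            if isinstance(c, BatchNorm):
                state[f"{c.prefix}.running_mean"] = c.running_mean.copy()
                state[f"{c.prefix}.running_var"] = c.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.data[...] = state[p.name]
        for c in self._iter_modules():
            if isinstance(c, BatchNorm):
                c.running_mean[...] = state[f"{c.prefix}.running_mean"]
                c.running_var[...] = state[f"{c.prefix}.running_var"]

    def _iter_modules(self):
        yield self
        for c in self._children:
            yield from c._iter_modules()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = [self.register(l) for l in layers]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class Conv1d(Module):
    """1-D convolution on (B, L, C_in) -> (B, ceil(L/stride), C_out).

    'Same'-style symmetric zero padding; implemented as a sum of strided
    batched matmuls over kernel taps, which keeps both passes inside BLAS.
    """

    def __init__(self, c_in, c_out, kernel, stride=1, rng=None, name="conv",
                 role="backbone", bias=True, dtype=np.float64):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        scale = np.sqrt(2.0 / (c_in * kernel))  # He init for GELU/ReLU nets
        self.W = self.add_param(
            rng.normal(0, scale, (c_out, c_in, kernel)).astype(dtype),
            f"{name}.W", role,
        )
        self.b = (
            self.add_param(np.zeros(c_out, dtype), f"{name}.b", role, decay=False)
            if bias else None
        )

    def _pad(self, L: int) -> tuple[int, int, int]:
        L_out = -(-L // self.stride)  # ceil
        needed = (L_out - 1) * self.stride + self.k
        pad = max(0, needed - L)
        return L_out, pad // 2, pad - pad // 2

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, _ = x.shape
        L_out, pl, pr = self._pad(L)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        y = np.zeros((B, L_out, self.c_out), dtype=x.dtype)
        W = self.W.data
        for k in range(self.k):
            xs = xp[:, k : k + (L_out - 1) * self.stride + 1 : self.stride, :]
            y += xs @ W[:, :, k].T
        if self.b is not None:
            y += self.b.data
        self._cache = (xp, x.shape, L_out, pl)
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        xp, x_shape, L_out, pl = self._cache
        W = self.W.data
        gxp = np.zeros_like(xp)
        for k in range(self.k):
            sl = slice(k, k + (L_out - 1) * self.stride + 1, self.stride)
            xs = xp[:, sl, :]
            self.W.grad[:, :, k] += np.tensordot(g, xs, axes=([0, 1], [0, 1]))
            gxp[:, sl, :] += g @ W[:, :, k]
        if self.b is not None:
            self.b.grad += g.sum(axis=(0, 1))
        L = x_shape[1]
        return gxp[:, pl : pl + L, :]


class BatchNorm(Module):
    """Batch normalization per channel over the (batch, time) axes."""

    def __init__(self, c, momentum=0.1, eps=1e-5, name="bn", role="backbone",
                 dtype=np.float64):
        super().__init__()
        self.prefix = name
        self.eps, self.momentum = eps, momentum
        self.gamma = self.add_param(np.ones(c, dtype), f"{name}.gamma", role, decay=False)
        self.beta = self.add_param(np.zeros(c, dtype), f"{name}.beta", role, decay=False)
        self.running_mean = np.zeros(c, dtype)
        self.running_var = np.ones(c, dtype)
        self._stats_seen = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            if not self._stats_seen:
                # seed the running stats with the first batch so eval mode
                # is usable after very few steps (no cold-start bias)
                self.running_mean[...] = mu
                self.running_var[...] = var
                self._stats_seen = True
            else:
                self.running_mean += self.momentum * (mu - self.running_mean)
                self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, x.shape[0] * x.shape[1])
        return self.gamma.data * xhat + self.beta.data

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv, n = self._cache
        self.gamma.grad += (g * xhat).sum(axis=(0, 1))
        self.beta.grad += g.sum(axis=(0, 1))
        if not self.training:
            return g * self.gamma.data * inv
        gx = g * self.gamma.data
        return (inv / n) * (
            n * gx
            - gx.sum(axis=(0, 1))
            - xhat * (gx * xhat).sum(axis=(0, 1))
        )


class Linear(Module):
    def __init__(self, d_in, d_out, rng=None, name="fc", role="classifier",
                 dtype=np.float64):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / d_in)
        self.W = self.add_param(
            rng.normal(0, scale, (d_in, d_out)).astype(dtype), f"{name}.W", role
        )
        self.b = self.add_param(np.zeros(d_out, dtype), f"{name}.b", role, decay=False)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        self.W.grad += np.tensordot(x, g, axes=(list(range(x.ndim - 1)),) * 2)
        self.b.grad += g.reshape(-1, g.shape[-1]).sum(axis=0)
        return g @ self.W.data.T


class LayerNorm(Module):
    def __init__(self, d, eps=1e-5, name="ln", role="attention",
                 dtype=np.float64):
        super().__init__()
        self.eps = eps
        self.gamma = self.add_param(np.ones(d, dtype), f"{name}.gamma", role, decay=False)
        self.beta = self.add_param(np.zeros(d, dtype), f"{name}.beta", role, decay=False)

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gamma.data * xhat + self.beta.data

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        d = xhat.shape[-1]
        self.gamma.grad += (g * xhat).sum(axis=tuple(range(g.ndim - 1)))
        self.beta.grad += g.sum(axis=tuple(range(g.ndim - 1)))
        gx = g * self.gamma.data
        return (inv / d) * (
            d * gx
            - gx.sum(axis=-1, keepdims=True)
            - xhat * (gx * xhat).sum(axis=-1, keepdims=True)
        )


class GELU(Module):
    """Exact Gaussian-error-linear unit: x * Phi(x)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        self._cache = (x, cdf)
        return x * cdf

    def backward(self, g: np.ndarray) -> np.ndarray:
        x, cdf = self._cache
        pdf = np.exp(-0.5 * x * x) * (1.0 / math.sqrt(2.0 * math.pi))
        return g * (cdf + x * pdf)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class Dropout(Module):
    """Inverted dropout; identity in eval mode.  The RNG is injected via
    ``Module.set_rng`` so whole-model runs are seeded from one stream."""

    def __init__(self, p: float):
        super().__init__()
        self.p = p
        self.rng = np.random.default_rng(0)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) * (
            1.0 / (1.0 - self.p)
        )
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


class MultiHeadSelfAttention(Module):
    """Scaled dot-product attention over (B, L, D), h parallel heads.

    softmax(Q K^T / sqrt(d_k)) V per head, heads concatenated and
    output-projected; shape-preserving.
    """

    def __init__(self, d_model, n_heads, rng=None, name="mhsa", role="attention",
                 dtype=np.float64):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.d, self.h = d_model, n_heads
        self.dk = d_model // n_heads
        rng = rng or np.random.default_rng(0)
        mk = lambda nm: self.register(
            Linear(d_model, d_model, rng, name=f"{name}.{nm}", role=role,
                   dtype=dtype)
        )
        self.wq, self.wk, self.wv, self.wo = mk("q"), mk("k"), mk("v"), mk("o")

    def _split(self, x):  # (B,L,D) -> (B,h,L,dk)
        B, L, _ = x.shape
        return x.reshape(B, L, self.h, self.dk).transpose(0, 2, 1, 3)

    def _merge(self, x):  # (B,h,L,dk) -> (B,L,D)
        B, h, L, dk = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, L, h * dk)

    def forward(self, x: np.ndarray) -> np.ndarray:
        q = self._split(self.wq.forward(x))
        k = self._split(self.wk.forward(x))
        v = self._split(self.wv.forward(x))
        scores = q @ k.transpose(0, 1, 3, 2) / math.sqrt(self.dk)
        attn = softmax(scores, axis=-1)
        ctx = attn @ v
        self._cache = (q, k, v, attn)
        return self.wo.forward(self._merge(ctx))

    def attention_weights(self) -> np.ndarray:
        """Attention probabilities of the last forward pass (B, h, L, L)."""
        return self._cache[3]

    def backward(self, g: np.ndarray) -> np.ndarray:
        q, k, v, attn = self._cache
        g_ctx = self._split(self.wo.backward(g))
        g_attn = g_ctx @ v.transpose(0, 1, 3, 2)
        g_v = attn.transpose(0, 1, 3, 2) @ g_ctx
        # softmax backward per row
        g_scores = attn * (g_attn - (g_attn * attn).sum(axis=-1, keepdims=True))
        g_scores /= math.sqrt(self.dk)
        g_q = g_scores @ k
        g_k = g_scores.transpose(0, 1, 3, 2) @ q
        gx = self.wq.backward(self._merge(g_q))
        gx += self.wk.backward(self._merge(g_k))
        gx += self.wv.backward(self._merge(g_v))
        return gx


class PositionalEncoding(Module):
    """Fixed sinusoidal positional table added to (B, L, D)."""

    def __init__(self, d_model, max_len, dtype=np.float64):
        super().__init__()
        self.dtype = dtype
        pos = np.arange(max_len)[:, None]
        i = np.arange(0, d_model, 2)[None, :]
        angles = pos / np.power(10000.0, i / d_model)
        pe = np.zeros((max_len, d_model))
        pe[:, 0::2] = np.sin(angles)
        pe[:, 1::2] = np.cos(angles[:, : d_model // 2 + d_model % 2])[
            :, : pe[:, 1::2].shape[1]
        ]
        self.table = pe.astype(dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x + self.table[: x.shape[1]]

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g


class MaxAvgFuse(Module):
    """Global max + average pooling over time, concatenated: (B,L,D)->(B,2D).

    ``mode="avg"`` keeps only the average branch (the fusion-ablation
    variant), giving a (B, D) output.
    """

    def __init__(self, mode: str = "maxavg"):
        super().__init__()
        if mode not in ("maxavg", "avg"):
            raise ValueError("mode must be 'maxavg' or 'avg'")
        self.mode = mode

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] < 1:
            raise ValueError("empty time axis")
        y_avg = x.mean(axis=1)
        if self.mode == "avg":
            self._cache = (x.shape, None)
            return y_avg
        idx = x.argmax(axis=1)
        y_max = np.take_along_axis(x, idx[:, None, :], axis=1)[:, 0, :]
        self._cache = (x.shape, idx)
        return np.concatenate([y_max, y_avg], axis=1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        shape, idx = self._cache
        B, L, D = shape
        gx = np.zeros(shape, dtype=g.dtype)
        if self.mode == "avg":
            gx += g[:, None, :] / L
            return gx
        g_max, g_avg = g[:, :D], g[:, D:]
        gx += g_avg[:, None, :] / L
        np.put_along_axis(
            gx, idx[:, None, :],
            np.take_along_axis(gx, idx[:, None, :], axis=1) + g_max[:, None, :],
            axis=1,
        )
        return gx
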