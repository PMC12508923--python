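"""Minimal numpy neural-network layers with explicit reverse-mode gradients.

Every layer caches what its backward pass needs during ``forward`` and
returns the gradient with respect to its input from ``backward`` while
accumulating parameter gradients in place.  Convolutional tensors are
channel-first ``(channels, batch, length)`` -- this layout turns a 1-D
convolution into one channel-mixing matmul per kernel tap with no im2col
copies and no per-layer transposes, which matters for narrow CPU-sized
networks.  Transformer tensors are ``(batch, tokens, embed)``.

The engine is deliberately small: only the operations the 1-D encoder-
decoder architectures need, each with a numerically checked adjoint.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = [
    "Parameter", "Module", "Sequential", "Conv1d", "ConvTranspose1d",
    "MaxPool1d", "PReLU", "Tanh", "Linear", "LayerNorm",
    "MultiHeadSelfAttention", "FeedForward", "TransformerLayer", "gelu",
]


class Parameter:
    """A trainable array and its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base class: recursive parameter collection over attributes."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params: list[Parameter], seen: set[int]) -> None:
        for value in vars(self).values():
            self._collect_value(value, params, seen)

    @staticmethod
    def _collect_value(value, params: list[Parameter], seen: set[int]) -> None:
        if isinstance(value, Parameter):
            if id(value) not in seen:
                seen.add(id(value))
                params.append(value)
        elif isinstance(value, Module):
            value._collect(params, seen)
        elif isinstance(value, (list, tuple)):
            for v in value:
                Module._collect_value(v, params, seen)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


# ---------------------------------------------------------------------------
# convolutional layers

class Conv1d(Module):
    """Same-padded 1-D convolution (stride 1), He-initialised.

    Operates on channel-first ``(c_in, batch, length)`` tensors; weight
    layout is ``(kernel, c_out, c_in)``.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        pad = (kernel - 1) // 2
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.c_in, self.c_out, self.kernel, self.pad = c_in, c_out, kernel, pad
        self.weight = Parameter(
            (rng.standard_normal((kernel, c_out, c_in)) * scale).astype(dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype))
        self._xp: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, n, length = x.shape
        lp = length + 2 * self.pad
        xp = np.zeros((c, n, lp), dtype=x.dtype)
        xp[:, :, self.pad:self.pad + length] = x
        x2 = xp.reshape(c, n * lp)
        self._xp, self._shape = xp, (c, n, length)
        w = self.weight.value
        acc = np.zeros((self.c_out, n, length), dtype=x.dtype)
        for k in range(self.kernel):
            acc += (w[k] @ x2).reshape(self.c_out, n, lp)[:, :, k:k + length]
        acc += self.bias.value[:, None, None]
        return acc

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, n, length = self._shape
        xp = self._xp
        w = self.weight.value  # (k, c_out, c)
        dyt = np.ascontiguousarray(dy).reshape(self.c_out, n * length)
        self.bias.grad += dyt.sum(axis=1)
        # all taps in one GEMM: (k*c, c_out) @ (c_out, n*length)
        w_cat = np.ascontiguousarray(w.transpose(0, 2, 1)).reshape(
            self.kernel * c, self.c_out)
        dtaps = (w_cat @ dyt).reshape(self.kernel, c, n, length)
        dxp = np.zeros_like(xp)
        for k in range(self.kernel):
            xk = xp[:, :, k:k + length].reshape(c, n * length)
            self.weight.grad[k] += dyt @ xk.T
            dxp[:, :, k:k + length] += dtaps[k]
        if not self.pad:
            return dxp
        return np.ascontiguousarray(dxp[:, :, self.pad:self.pad + length])


class ConvTranspose1d(Module):
    """Transposed convolution with kernel = stride (non-overlapping
    upsampling, doubles the length for kernel 2).  Channel-first tensors;
    weight layout ``(kernel, c_out, c_in)``."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / c_in)
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.weight = Parameter(
            (rng.standard_normal((kernel, c_out, c_in)) * scale).astype(dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype))
        self._x2: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, n, length = x.shape
        x2 = np.ascontiguousarray(x).reshape(c, n * length)
        self._x2, self._shape = x2, (c, n, length)
        y = np.empty((self.c_out, n, length * self.kernel), dtype=x.dtype)
        for k in range(self.kernel):
            y[:, :, k::self.kernel] = (self.weight.value[k] @ x2).reshape(
                self.c_out, n, length)
        y += self.bias.value[:, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, n, length = self._shape
        dx2 = np.zeros((c, n * length), dtype=dy.dtype)
        for k in range(self.kernel):
            dyk = np.ascontiguousarray(dy[:, :, k::self.kernel]).reshape(
                self.c_out, n * length)
            self.weight.grad[k] += dyk @ self._x2.T
            dx2 += self.weight.value[k].T @ dyk
        self.bias.grad += dy.sum(axis=(1, 2))
        return dx2.reshape(c, n, length)


class MaxPool1d(Module):
    """Non-overlapping max pooling (kernel = stride = 2 halves the length)."""

    def __init__(self, kernel: int = 2):
        self.kernel = kernel
        self._argmax: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, n, length = x.shape
        if length % self.kernel:
            raise ValueError(f"length {length} not divisible by pool {self.kernel}")
        xr = x.reshape(c, n, length // self.kernel, self.kernel)
        self._argmax = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, n, length = self._shape
        dxr = np.zeros((c, n, length // self.kernel, self.kernel), dtype=dy.dtype)
        np.put_along_axis(dxr, self._argmax[..., None], dy[..., None], axis=3)
        return dxr.reshape(c, n, length)


class PReLU(Module):
    """Parametric ReLU with one learnable slope per channel (init 0.25);
    channel-first tensors."""

    def __init__(self, channels: int, dtype=np.float32):
        self.alpha = Parameter(np.full(channels, 0.25, dtype=dtype))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        a = self.alpha.value[:, None, None]
        return np.where(x > 0, x, a * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        neg = x <= 0
        self.alpha.grad += np.where(neg, dy * x, 0.0).sum(axis=(1, 2))
        a = self.alpha.value[:, None, None]
        return np.where(neg, a * dy, dy)


class Tanh(Module):
    def __init__(self):
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * (1.0 - self._y ** 2)


# ---------------------------------------------------------------------------
# dense / transformer layers

class Linear(Module):
    """Affine map on the last axis, Xavier-initialised."""

    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / (f_in + f_out))
        self.weight = Parameter((rng.standard_normal((f_in, f_out)) * scale).astype(dtype))
        self.bias = Parameter(np.zeros(f_out, dtype=dtype))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.weight.grad += x2.T @ dy2
        self.bias.grad += dy2.sum(axis=0)
        return dy @ self.weight.value.T


class LayerNorm(Module):
    """Layer normalization over the last axis with learnable scale/shift."""

    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Parameter(np.ones(dim, dtype=dtype))
        self.beta = Parameter(np.zeros(dim, dtype=dtype))
        self.eps = eps
        self._xhat: np.ndarray | None = None
        self._inv_std: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._xhat, self._inv_std = xhat, inv_std
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        axes = tuple(range(dy.ndim - 1))
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.value
        return inv_std * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )


_SQRT2 = np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x: np.ndarray) -> np.ndarray:
    """Gaussian error linear unit (exact erf form)."""
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * _INV_SQRT2PI * np.exp(-0.5 * x * x)


class _Gelu(Module):
    def __init__(self):
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return gelu(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * _gelu_grad(self._x)


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product multi-head self-attention on
    (batch, tokens, embed) tensors."""

    def __init__(self, embed: int, n_heads: int, rng: np.random.Generator,
                 dtype=np.float32):
        if embed % n_heads:
            raise ValueError(f"embed {embed} not divisible by {n_heads} heads")
        self.embed, self.n_heads, self.d_head = embed, n_heads, embed // n_heads
        self.qkv = Linear(embed, 3 * embed, rng, dtype)
        self.proj = Linear(embed, embed, rng, dtype)
        self._cache = None

    def _split(self, x: np.ndarray) -> np.ndarray:
        n, t, _ = x.shape
        return x.reshape(n, t, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        n, h, t, d = x.shape
        return np.ascontiguousarray(x.transpose(0, 2, 1, 3)).reshape(n, t, h * d)

    def forward(self, x: np.ndarray) -> np.ndarray:
        qkv = self.qkv.forward(x)
        q, k, v = np.split(qkv, 3, axis=-1)
        q, k, v = self._split(q), self._split(k), self._split(v)  # (n,h,t,d)
        scale = 1.0 / np.sqrt(self.d_head)
        scores = np.einsum("nhtd,nhsd->nhts", q, k, optimize=True) * scale
        scores -= scores.max(axis=-1, keepdims=True)
        attn = np.exp(scores)
        attn /= attn.sum(axis=-1, keepdims=True)
        ctx = np.einsum("nhts,nhsd->nhtd", attn, v, optimize=True)
        self._cache = (q, k, v, attn)
        return self.proj.forward(self._merge(ctx))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        q, k, v, attn = self._cache
        dctx = self._split(self.proj.backward(dy))
        dattn = np.einsum("nhtd,nhsd->nhts", dctx, v, optimize=True)
        dv = np.einsum("nhts,nhtd->nhsd", attn, dctx, optimize=True)
        # softmax adjoint
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        scale = 1.0 / np.sqrt(self.d_head)
        dscores *= scale
        dq = np.einsum("nhts,nhsd->nhtd", dscores, k, optimize=True)
        dk = np.einsum("nhts,nhtd->nhsd", dscores, q, optimize=True)
        dqkv = np.concatenate(
            [self._merge(dq), self._merge(dk), self._merge(dv)], axis=-1)
        return self.qkv.backward(dqkv)


class FeedForward(Module):
    """Transformer MLP block: Linear -> GELU -> Linear, hidden = 4x embed."""

    def __init__(self, embed: int, rng: np.random.Generator, hidden: int | None = None,
                 dtype=np.float32):
        hidden = hidden or 4 * embed
        self.net = Sequential(Linear(embed, hidden, rng, dtype), _Gelu(),
                              Linear(hidden, embed, rng, dtype))

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy)


class TransformerLayer(Module):
    """Pre-norm residual transformer layer:
    ``z' = MSA(LN(z)) + z``; ``z_out = MLP(LN(z')) + z'``."""

    def __init__(self, embed: int, n_heads: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.ln1 = LayerNorm(embed, dtype=dtype)
        self.msa = MultiHeadSelfAttention(embed, n_heads, rng, dtype)
        self.ln2 = LayerNorm(embed, dtype=dtype)
        self.mlp = FeedForward(embed, rng, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = self.msa.forward(self.ln1.forward(x)) + x
        return self.mlp.forward(self.ln2.forward(x)) + x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.ln2.backward(self.mlp.backward(dy)) + dy
        return self.ln1.backward(self.msa.backward(dy)) + dy
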