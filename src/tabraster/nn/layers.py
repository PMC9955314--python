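"""Minimal CPU neural-network layers with hand-derived backpropagation.

Implements exactly the operations a residual image classifier needs —
strided convolution (via im2col / matrix multiply), batch normalization,
ReLU, max and global-average pooling, fully connected layers and softmax
cross-entropy — as plain numpy, NCHW layout. Every layer caches what its
backward pass needs during a ``train=True`` forward call; inference-only
forwards skip the caches. Gradients are verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Module",
    "Chain",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "softmax_cross_entropy",
]


class Param:
    """A trainable tensor with its gradient and optimizer state."""

    __slots__ = ("data", "grad", "velocity", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = data
        self.grad = np.zeros_like(data)
        self.velocity = np.zeros_like(data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x, train=False):
        return self.forward(x, train=train)


class Chain(Module):
    """Sequential composition of modules."""

    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def params(self):
        return [p for m in self.modules for p in m.params()]

    def forward(self, x, train=False):
        for m in self.modules:
            x = m.forward(x, train=train)
        return x

    def backward(self, dout):
        for m in reversed(self.modules):
            dout = m.backward(dout)
        return dout


def _out_size(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


class Conv2d(Module):
    """2-D convolution (cross-correlation), NCHW, no groups/dilation.

    Initialization is He-normal scaled by the fan-in, the standard choice
    for ReLU networks.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        bias: bool = False,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, kernel, kernel))
        self.weight = Param(w.astype(dtype), "conv.weight")
        self.bias = Param(np.zeros(out_ch, dtype=dtype), "conv.bias") if bias else None
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._cache = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias else [])

    def forward(self, x, train=False):
        k, s, p = self.kernel, self.stride, self.pad
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (n, c, ho, wo, k, k) -> (n, ho, wo, c*k*k)
        ho, wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n, ho, wo, c * k * k
        )
        wm = self.weight.data.reshape(self.weight.data.shape[0], -1)
        out = cols @ wm.T
        if self.bias:
            out = out + self.bias.data
        if train:
            self._cache = (cols, x.shape, xp.shape)
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dout):
        cols, x_shape, xp_shape = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        n, c, h, w = x_shape
        o = dout.shape[1]
        ho, wo = dout.shape[2], dout.shape[3]
        dflat = dout.transpose(0, 2, 3, 1)  # (n, ho, wo, o)
        wm = self.weight.data.reshape(o, -1)
        self.weight.grad += np.tensordot(
            dflat, cols, axes=([0, 1, 2], [0, 1, 2])
        ).reshape(self.weight.data.shape)
        if self.bias:
            self.bias.grad += dflat.sum(axis=(0, 1, 2))
        dcols = (dflat @ wm).reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros(xp_shape, dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, i, j]
        self._cache = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        self.gamma = Param(np.ones(channels, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.eps, self.momentum = eps, momentum
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(self.running_mean.dtype)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv[:, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma.data[:, None, None] * xhat + self.beta.data[:, None, None]

    def backward(self, dout):
        xhat, inv = self._cache
        nhw = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.data[:, None, None]
        # standard batchnorm backward, vectorized over channels
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[:, None, None]
        del nhw
        self._cache = None
        return dx


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._cache = None

    def forward(self, x, train=False):
        k, s, p = self.kernel, self.stride, self.pad
        xp = (
            np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
            if p
            else x
        )
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo = win.shape[:4]
        flat = win.reshape(n, c, ho, wo, k * k)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (arg, x.shape, xp.shape)
        return out

    def backward(self, dout):
        arg, x_shape, xp_shape = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        n, c, h, w = x_shape
        hp, wp = xp_shape[2], xp_shape[3]
        ho, wo = arg.shape[2], arg.shape[3]
        iy, ix = np.divmod(arg, k)
        oy = np.arange(ho)[None, None, :, None] * s
        ox = np.arange(wo)[None, None, None, :] * s
        flat_idx = (oy + iy) * wp + (ox + ix)
        dxp = np.zeros((n, c, hp * wp), dtype=dout.dtype)
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (ni, ci, flat_idx), dout)
        dxp = dxp.reshape(n, c, hp, wp)
        self._cache = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class GlobalAvgPool(Module):
    """Spatial mean -> (n, c) feature vectors."""

    def __init__(self):
        self._shape = None

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        else:
            self._shape = x.shape  # cheap; needed if backward follows eval tap
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(
            dout[:, :, None, None] / (h * w), (n, c, h, w)
        ).astype(dout.dtype)


class Flatten(Module):
    def __init__(self):
        self._shape = None

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / in_dim), (out_dim, in_dim))
        self.weight = Param(w.astype(dtype), "linear.weight")
        self.bias = Param(np.zeros(out_dim, dtype=dtype), "linear.bias")
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dout):
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        dx = dout @ self.weight.data
        self._x = None
        return dx


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy of softmax(logits) against integer labels.

    Returns ``(loss, dlogits)`` with the gradient already averaged over the
    batch.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(probs[np.arange(n), labels] + 1e-12).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(logits.dtype)
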