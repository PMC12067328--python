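"""Layers with explicit forward/backward passes (batch size 1, channels first).

Convolutions use TensorFlow-style "same" padding: for input extent ``n``,
kernel ``k`` and stride ``s`` the total padding is
``max((ceil(n/s) - 1) * s + k - n, 0)``, split left-light/right-heavy, so a
stride-2 layer maps ``n -> ceil(n/2)`` and a stride-1 layer preserves the
extent.  Transposed convolution is the exact linear adjoint of the
corresponding stride-``s`` convolution, so it maps ``n -> s * n``.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Module", "Sequential",
    "Conv3d", "ConvTranspose3d", "BatchNorm3d", "Dropout",
    "LeakyReLU", "ReLU", "Tanh", "Sigmoid",
]


class Param:
    """A learnable array and its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Module:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy


# ---------------------------------------------------------------------------
# convolution geometry


def same_pads(n: int, k: int, s: int) -> tuple[int, int]:
    total = max((math.ceil(n / s) - 1) * s + k - n, 0)
    return total // 2, total - total // 2


def conv_out_size(n: int, s: int) -> int:
    return math.ceil(n / s)


def _im2col(x: np.ndarray, k: int, s: int, pads) -> tuple[np.ndarray, tuple]:
    """(C, D, H, W) -> (n_out_voxels, C*k^3) patch matrix."""
    xp = np.pad(x, ((0, 0), *pads))
    out_sp = tuple(conv_out_size(n, s) for n in x.shape[1:])
    win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    win = win[:, ::s, ::s, ::s][:, :out_sp[0], :out_sp[1], :out_sp[2]]
    cols = win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(int(np.prod(out_sp)), -1)
    return np.ascontiguousarray(cols), out_sp


def _col2im(gcols: np.ndarray, in_sp: tuple, c: int, k: int, s: int, pads,
            dtype) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patches back to (C, D, H, W)."""
    padded = tuple(n + p[0] + p[1] for n, p in zip(in_sp, pads))
    out_sp = tuple(conv_out_size(n, s) for n in in_sp)
    g6 = gcols.reshape(*out_sp, c, k, k, k).transpose(3, 0, 1, 2, 4, 5, 6)
    gxp = np.zeros((c, *padded), dtype=dtype)
    for kz in range(k):
        for ky in range(k):
            for kx in range(k):
                gxp[:,
                    kz:kz + s * out_sp[0]:s,
                    ky:ky + s * out_sp[1]:s,
                    kx:kx + s * out_sp[2]:s] += g6[:, :, :, :, kz, ky, kx]
    sl = tuple(slice(p[0], p[0] + n) for p, n in zip(pads, in_sp))
    return gxp[(slice(None), *sl)]


class Conv3d(Module):
    """Strided 3D convolution, weights ~ N(0, 0.02) (pix2pix convention)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 4, stride: int = 2,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch, self.k, self.s = in_ch, out_ch, kernel, stride
        self.w = Param(rng.normal(0.0, 0.02, (in_ch * kernel ** 3, out_ch)).astype(dtype), "conv_w")
        self.b = Param(np.zeros(out_ch, dtype=dtype), "conv_b")

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        pads = tuple(same_pads(n, self.k, self.s) for n in x.shape[1:])
        cols, out_sp = _im2col(x, self.k, self.s, pads)
        y = cols @ self.w.value + self.b.value
        self._cache = (cols, x.shape[1:], pads, out_sp, x.dtype)
        return y.reshape(*out_sp, self.out_ch).transpose(3, 0, 1, 2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, in_sp, pads, out_sp, dtype = self._cache
        gyf = gy.transpose(1, 2, 3, 0).reshape(-1, self.out_ch)
        self.w.grad += cols.T @ gyf
        self.b.grad += gyf.sum(axis=0)
        gcols = gyf @ self.w.value.T
        return _col2im(gcols, in_sp, self.in_ch, self.k, self.s, pads, dtype)


class ConvTranspose3d(Module):
    """Stride-``s`` transposed 3D convolution mapping extent ``n -> s*n``.

    Implemented as the adjoint of the equivalent forward convolution
    (extent ``s*n -> n``), sharing the im2col machinery.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 4, stride: int = 2,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch, self.k, self.s = in_ch, out_ch, kernel, stride
        # weight of the *equivalent* conv: (out_ch * k^3, in_ch)
        self.w = Param(rng.normal(0.0, 0.02, (out_ch * kernel ** 3, in_ch)).astype(dtype), "tconv_w")
        self.b = Param(np.zeros(out_ch, dtype=dtype), "tconv_b")

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        out_sp = tuple(self.s * n for n in x.shape[1:])
        pads = tuple(same_pads(n, self.k, self.s) for n in out_sp)
        xf = x.transpose(1, 2, 3, 0).reshape(-1, self.in_ch)
        gcols = xf @ self.w.value.T
        y = _col2im(gcols, out_sp, self.out_ch, self.k, self.s, pads, x.dtype)
        self._cache = (xf, out_sp, pads)
        return y + self.b.value[:, None, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xf, out_sp, pads = self._cache
        cols, in_sp_small = _im2col(gy, self.k, self.s, pads)
        self.w.grad += cols.T @ xf
        self.b.grad += gy.sum(axis=(1, 2, 3))
        gx = cols @ self.w.value
        return gx.reshape(*in_sp_small, self.in_ch).transpose(3, 0, 1, 2)


class BatchNorm3d(Module):
    """Per-channel normalisation over the spatial axes (batch of one).

    Training uses the statistics of the current volume and maintains
    running averages (momentum 0.1) for inference.
    """

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(rng.normal(1.0, 0.02, n_ch).astype(dtype), "bn_gamma")
        self.beta = Param(np.zeros(n_ch, dtype=dtype), "bn_beta")
        self.running_mean = np.zeros(n_ch, dtype=dtype)
        self.running_var = np.ones(n_ch, dtype=dtype)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        ax = (1, 2, 3)
        if training:
            mu = x.mean(axis=ax)
            var = x.var(axis=ax)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(self.running_mean.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(self.running_var.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None, None]) * inv[:, None, None, None]
        self._cache = (xhat, inv, training)
        return self.gamma.value[:, None, None, None] * xhat + self.beta.value[:, None, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv, training = self._cache
        ax = (1, 2, 3)
        n = float(np.prod(gy.shape[1:]))
        self.gamma.grad += (gy * xhat).sum(axis=ax)
        self.beta.grad += gy.sum(axis=ax)
        g = gy * self.gamma.value[:, None, None, None]
        if not training:
            return g * inv[:, None, None, None]
        gsum = g.sum(axis=ax, keepdims=True)
        gxhat_sum = (g * xhat).sum(axis=ax, keepdims=True)
        return inv[:, None, None, None] * (g - gsum / n - xhat * gxhat_sum / n)


class Dropout(Module):
    """Inverted dropout; active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy if self._mask is None else gy * self._mask


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, training: bool = True):
        self._neg = x < 0
        return np.where(self._neg, self.slope * x, x)

    def backward(self, gy):
        return np.where(self._neg, self.slope * gy, gy)


class ReLU(Module):
    def forward(self, x, training: bool = True):
        self._neg = x < 0
        return np.where(self._neg, 0.0, x)

    def backward(self, gy):
        return np.where(self._neg, 0.0, gy)


class Tanh(Module):
    def forward(self, x, training: bool = True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, gy):
        return gy * (1.0 - self._y ** 2)


class Sigmoid(Module):
    def forward(self, x, training: bool = True):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)
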