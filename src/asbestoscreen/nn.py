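"""Minimal NumPy neural-network layers with explicit backpropagation.

Small, dependency-free building blocks sized for desk-scale volumetric
training: N-dimensional convolutions via im2col/GEMM (2-D for slice models,
3-D for volume models), dense layers, ReLU, nearest-neighbour upsampling,
global average pooling, and Adam.  Layers cache what their backward pass
needs; ``backward`` consumes the gradient w.r.t. the layer output,
accumulates parameter gradients, and returns the gradient w.r.t. the input
(which is what makes input-gradient saliency maps free).

Shapes follow the channels-first convention ``(batch, channels, *spatial)``.
Convolutions use odd kernels with "same" padding, so the output spatial size
is ``ceil(size / stride)``.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

__all__ = [
    "Parameter",
    "ConvNd",
    "Dense",
    "ReLU",
    "Upsample2x",
    "GlobalAvgPool",
    "Adam",
    "sigmoid",
    "bce_with_logits",
]


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy from logits (numerically stable).

    ``L = mean(y * softplus(-z) + (1 - y) * softplus(z))``; works for hard
    (0/1) and soft (fractional) targets.  Returns ``(loss, dL/dlogits)``.
    """
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    softplus = np.logaddexp(0.0, z)
    loss = float(np.mean(y * (softplus - z) + (1.0 - y) * softplus))
    grad = (sigmoid(z) - y) / z.size
    return loss, grad


def _tupled(x, n: int) -> tuple[int, ...]:
    return tuple(x) if isinstance(x, (tuple, list)) else (int(x),) * n


class ConvNd:
    """Convolution over 2 or 3 spatial dimensions with "same" padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel, stride=1, rng: np.random.Generator | None = None):
        self.kernel = tuple(int(k) for k in (kernel if isinstance(kernel, (tuple, list)) else (kernel,)))
        if any(k % 2 == 0 for k in self.kernel):
            raise ValueError("kernels must be odd for same-padding")
        self.ndim = len(self.kernel)
        self.stride = _tupled(stride, self.ndim)
        self.pad = tuple(k // 2 for k in self.kernel)
        self.in_ch, self.out_ch = in_ch, out_ch
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * math.prod(self.kernel)
        self.w = Parameter(rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(out_ch, fan_in)))
        self.b = Parameter(np.zeros(out_ch))
        self._idx_cache: dict = {}

    def parameters(self):
        return [self.w, self.b]

    def _im2col(self, x: np.ndarray):
        pad = [(0, 0), (0, 0)] + [(p, p) for p in self.pad]
        xp = np.pad(x, pad)
        axes = tuple(range(2, 2 + self.ndim))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=axes)
        slicer = (slice(None), slice(None)) + tuple(slice(None, None, s) for s in self.stride)
        win = win[slicer]  # (B, C, *out, *kernel)
        out_spatial = win.shape[2 : 2 + self.ndim]
        b, c = x.shape[:2]
        p = math.prod(out_spatial)
        k = math.prod(self.kernel)
        # (B, P, C*K) with channel-major flattening to match the weight layout
        cols = np.ascontiguousarray(np.moveaxis(win.reshape(b, c, p, k), 1, 2)).reshape(b, p, c * k)
        return cols, out_spatial, xp.shape[2:]

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, out_spatial, padded_spatial = self._im2col(x)
        self._cols = cols
        self._in_shape = x.shape
        self._out_spatial = out_spatial
        self._padded_spatial = padded_spatial
        y = cols @ self.w.value.T + self.b.value
        return np.ascontiguousarray(np.moveaxis(y, 2, 1)).reshape(x.shape[0], self.out_ch, *out_spatial)

    def backward(self, gy: np.ndarray, need_input_grad: bool = True):
        b = gy.shape[0]
        p = math.prod(self._out_spatial)
        g = np.moveaxis(gy.reshape(b, self.out_ch, p), 1, 2)  # (B, P, out_ch)
        gflat = g.reshape(-1, self.out_ch)
        self.w.grad += gflat.T @ self._cols.reshape(-1, self.in_ch * math.prod(self.kernel))
        self.b.grad += gflat.sum(axis=0)
        if not need_input_grad:
            self._cols = None
            return None
        gcols = g @ self.w.value  # (B, P, C*K)
        gx = self._col2im(gcols, b)
        self._cols = None
        return gx

    def _col2im(self, gcols: np.ndarray, b: int):
        """Scatter column gradients back onto the (padded) input grid.

        Loops over the kernel offsets (27 for a 3x3x3 kernel) doing one
        strided vectorised add each, which is far cheaper than a per-element
        scatter.
        """
        c = self.in_ch
        out_sp = self._out_spatial
        k = self.kernel
        # (B, P, C*K) -> (B, C, *out_sp, *kernel)
        gr = np.moveaxis(gcols.reshape(b, math.prod(out_sp), c, math.prod(k)), 2, 1)
        gr = gr.reshape(b, c, *out_sp, *k)
        gxp = np.zeros((b, c) + self._padded_spatial, dtype=gcols.dtype)
        for offset in np.ndindex(*k):
            sl = tuple(
                slice(off, off + st * osz, st) for off, st, osz in zip(offset, self.stride, out_sp)
            )
            gxp[(slice(None), slice(None)) + sl] += gr[(slice(None), slice(None)) + (slice(None),) * self.ndim + offset]
        unpad = tuple(slice(p, p + s) for p, s in zip(self.pad, self._in_shape[2:]))
        return gxp[(slice(None), slice(None)) + unpad]


class Dense:
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = Parameter(rng.normal(0.0, math.sqrt(2.0 / in_features), size=(out_features, in_features)))
        self.b = Parameter(np.zeros(out_features))

    def parameters(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.w.grad += gy.T @ self._x
        self.b.grad += gy.sum(axis=0)
        gx = gy @ self.w.value
        self._x = None
        return gx


class ReLU:
    """Rectifier; a nonzero ``leak`` makes it leaky, which avoids dead units
    when the inputs are nonnegative (e.g. intensity images)."""

    def __init__(self, leak: float = 0.0):
        self.leak = leak

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        if self.leak == 0.0:
            return x * self._mask
        return np.where(self._mask, x, self.leak * x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = gy * self._mask if self.leak == 0.0 else gy * np.where(self._mask, 1.0, self.leak)
        self._mask = None
        return gx


class Upsample2x:
    """Nearest-neighbour x2 upsampling over all spatial axes."""

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._ndim = x.ndim - 2
        for ax in range(2, x.ndim):
            x = np.repeat(x, 2, axis=ax)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for ax in range(2, 2 + self._ndim):
            shape = gy.shape
            new = shape[:ax] + (shape[ax] // 2, 2) + shape[ax + 1 :]
            gy = gy.reshape(new).sum(axis=ax + 1)
        return gy


class GlobalAvgPool:
    """Mean over all spatial axes: (B, C, *S) -> (B, C)."""

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        axes = tuple(range(2, x.ndim))
        return x.mean(axis=axes)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        b, c = self._shape[:2]
        spatial = self._shape[2:]
        scale = 1.0 / math.prod(spatial)
        g = (gy * scale).reshape(b, c, *([1] * len(spatial)))
        return np.broadcast_to(g, self._shape).copy()


class Adam:
    """Adam with bias correction over a flat parameter list."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
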