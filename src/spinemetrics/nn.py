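"""Minimal NumPy neural-network layers for the segmentation U-Net.

Implements exactly what the segmenter needs -- same-padding 2-D
convolution (im2col), ReLU, 2x2 max-pooling, 2x2 nearest-neighbour
upsampling, channel concatenation, He-normal initialization, binary
cross-entropy on logits, and the Adam optimizer -- with explicit
forward/backward passes.  Everything is float32, deterministic given a
seeded ``numpy.random.Generator``, and verified against numerical
gradients in the test suite.

Tensors are (N, C, H, W).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "ReLU",
    "MaxPool2x2",
    "Upsample2x2",
    "Adam",
    "bce_with_logits",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) patch matrix, same padding."""
    n, c, h, w = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    v = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,H,W,k,k
    return np.ascontiguousarray(v.transpose(0, 1, 4, 5, 2, 3)).reshape(
        n, c * k * k, h * w
    )


def col2im(cols: np.ndarray, x_shape: tuple, k: int) -> np.ndarray:
    """Adjoint of :func:`im2col` (scatter-add of patch gradients)."""
    n, c, h, w = x_shape
    pad = k // 2
    cols = cols.reshape(n, c, k, k, h, w)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + h, j : j + w] += cols[:, :, i, j]
    return xp[:, :, pad : pad + h, pad : pad + w]


class Conv2d:
    """Same-padding convolution with He-normal weight init."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(cout, dtype=np.float32)
        self.k = k
        self.cin, self.cout = cin, cout
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        cols = im2col(x, self.k)
        out = np.matmul(self.w, cols) + self.b[None, :, None]
        if train:
            self._cache = (cols, x.shape)
        return out.reshape(n, self.cout, h, w)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        n, _, h, w = x_shape
        g = grad.reshape(n, self.cout, h * w)
        self.dw[...] = np.matmul(g, cols.transpose(0, 2, 1)).sum(axis=0)
        self.db[...] = g.sum(axis=(0, 2))
        dcols = np.matmul(self.w.T, g)
        return col2im(dcols, x_shape, self.k)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask

    def params(self):
        return []


class MaxPool2x2:
    """2x2 max pooling; input H, W must be even."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        v = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = v.max(axis=(3, 5))
        if train:
            self._cache = (x.shape, v == out[:, :, :, None, :, None])
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, mask = self._cache
        g = mask * grad[:, :, :, None, :, None]
        return g.reshape(x_shape)

    def params(self):
        return []


class Upsample2x2:
    """Nearest-neighbour 2x upsampling; backward sums 2x2 blocks."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))

    def params(self):
        return []


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy on logits.

    Returns (loss, dloss/dlogits); the stable log1p(exp(-|z|)) form.
    """
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    loss = np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z))))
    grad = (sigmoid(z) - y) / z.size
    return float(loss), grad.astype(np.float32)


class Adam:
    def __init__(self, params, lr: float = 5e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)  # list of (value, grad) array pairs
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (
                np.sqrt(self.v[i] / b2t) + self.eps
            )
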