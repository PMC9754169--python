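"""Minimal numpy convolutional-network backend.

Implements exactly the pieces the slice-reconstruction U-net needs —
3x3/1x1 same-padding convolutions (im2col + BLAS matmul), batch
normalization, 2x2 average pooling, nearest-neighbor upsampling,
inverted dropout and the Adam optimizer — with handwritten backward
passes. Layers cache their last forward activations, so a layer instance
serves one forward/backward cycle at a time (which is how the training
loop uses them). Everything is float32.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Param", "Conv2d", "BatchNorm2d", "ReLU", "AvgPool2", "Upsample2",
           "Dropout", "Adam"]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Conv2d:
    """Same-padding convolution with kernel size 1 or 3 (odd k in general)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.W = Param(rng.normal(0.0, scale, (out_channels, fan_in)))
        self.b = Param(np.zeros(out_channels))
        self.k = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        self._cache = None

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        N, C, H, W = x.shape
        k, p = self.k, self.k // 2
        if k == 1:
            cols = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(-1, C)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
            win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
            cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                                        ).reshape(N * H * W, C * k * k)
        y = cols @ self.W.value.T + self.b.value
        self._cache = (x.shape, cols)
        return np.ascontiguousarray(
            y.reshape(N, H, W, self.out_channels).transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        (N, C, H, W), cols = self._cache
        k, p = self.k, self.k // 2
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.out_channels)
        self.W.grad += dyf.T @ cols
        self.b.grad += dyf.sum(axis=0)
        dcols = dyf @ self.W.value
        if k == 1:
            return np.ascontiguousarray(dcols.reshape(N, H, W, C).transpose(0, 3, 1, 2))
        dcols = dcols.reshape(N, H, W, C, k, k)
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + H, dj:dj + W] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + H, p:p + W]


class BatchNorm2d:
    """Per-channel batch normalization over the (N, H, W) axes."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, x.shape) if training else None
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None]).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape = self._cache
        N, C, H, W = shape
        nt = N * H * W
        dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        dbeta = dy.sum(axis=(0, 2, 3))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.value[None, :, None, None] * inv_std[None, :, None, None]
        return (g * (dy - dbeta[None, :, None, None] / nt
                     - xhat * dgamma[None, :, None, None] / nt)).astype(np.float32)


class ReLU:
    def __init__(self):
        self._mask = None

    def parameters(self):
        return []

    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class AvgPool2:
    """2x2 average pooling; spatial dims must be even (guaranteed by padding)."""

    def parameters(self):
        return []

    def forward(self, x, training=False, rng=None):
        N, C, H, W = x.shape
        self._shape = x.shape
        return x.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5)).astype(np.float32)

    def backward(self, dy):
        N, C, H, W = self._shape
        up = np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3)
        return (up * 0.25).astype(np.float32)


class Upsample2:
    """Nearest-neighbor x2 upsampling."""

    def parameters(self):
        return []

    def forward(self, x, training=False, rng=None):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy):
        N, C, H, W = dy.shape
        return dy.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5)).astype(np.float32)


class Dropout:
    """Inverted dropout; active only in training mode with an RNG supplied."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask = None

    def parameters(self):
        return []

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an RNG for determinism")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return (x * self._mask).astype(np.float32)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(np.float32)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - b1) * (p.grad - m)
            v += (1.0 - b2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
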