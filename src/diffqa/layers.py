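"""Minimal numpy neural-network primitives for the quality network.

Each layer implements ``forward(x, train)`` and ``backward(dy)``; the
backward pass consumes intermediates cached by the most recent forward call
and accumulates parameter gradients into :class:`Param` objects.  Convolution
is an im2col + GEMM so the heavy lifting runs through BLAS.  All backward
passes are verified against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np


class Param:
    """A learnable array with its gradient accumulator."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = data
        self.grad = np.zeros_like(data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def kaiming_normal(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    fan_in: int,
    negative_slope: float = 0.0,
    dtype=np.float32,
) -> np.ndarray:
    """He-style normal initialization scaled for (leaky-)rectifier fan-in."""
    gain = np.sqrt(2.0 / (1.0 + negative_slope**2))
    std = gain / np.sqrt(fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Layer:
    def params(self) -> list[Param]:
        return []

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-learnable state (running statistics)."""
        return {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# ---------------------------------------------------------------------------


def _im2col(xp: np.ndarray, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    b, c, _, _ = xp.shape
    cols = np.empty((b, c, k, k, oh, ow), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * oh : stride,
                                  j : j + stride * ow : stride]
    return cols.reshape(b, c * k * k, oh * ow)


class Conv2d(Layer):
    """2D convolution, kernel k x k, zero padding k//2, configurable stride."""

    def __init__(self, name: str, in_channels: int, out_channels: int,
                 kernel_size: int, stride: int, rng: np.random.Generator,
                 negative_slope: float, dtype=np.float32):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.stride = stride
        self.pad = kernel_size // 2
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Param(
            f"{name}.weight",
            kaiming_normal(rng, (out_channels, fan_in), fan_in,
                           negative_slope, dtype),
        )
        self.bias = Param(f"{name}.bias", np.zeros(out_channels, dtype=dtype))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        oh = (h + 2 * self.pad - self.k) // self.stride + 1
        ow = (w + 2 * self.pad - self.k) // self.stride + 1
        return oh, ow

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        oh, ow = self._out_hw(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        cols = _im2col(xp, self.k, self.stride, oh, ow)
        y = np.matmul(self.weight.data, cols)  # (b, out_c, oh*ow)
        y += self.bias.data[None, :, None]
        self._cache = (cols, (b, c, h, w), (oh, ow))
        return y.reshape(b, self.out_channels, oh, ow)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (b, c, h, w), (oh, ow) = self._cache
        dyf = dy.reshape(b, self.out_channels, oh * ow)
        self.weight.grad += np.matmul(dyf, cols.transpose(0, 2, 1)).sum(axis=0)
        self.bias.grad += dyf.sum(axis=(0, 2))
        dcols = np.matmul(self.weight.data.T, dyf)  # (b, c*k*k, oh*ow)
        dcols = dcols.reshape(b, c, self.k, self.k, oh, ow)
        hp, wp = h + 2 * self.pad, w + 2 * self.pad
        dxp = np.zeros((b, c, hp, wp), dtype=dy.dtype)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += dcols[:, :, i, j]
        return dxp[:, :, self.pad : self.pad + h, self.pad : self.pad + w]


class BatchNorm2d(Layer):
    def __init__(self, name: str, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5, dtype=np.float32):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(f"{name}.gamma", np.ones(channels, dtype=dtype))
        self.beta = Param(f"{name}.beta", np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def buffers(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            n = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var * n / max(n - 1, 1)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mean
            self.running_var[...] = (1 - m) * self.running_var + m * unbiased
        else:
            mean = self.running_mean
            var = self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        self._cache = (xhat, invstd, train)
        return self.gamma.data[None, :, None, None] * xhat + \
            self.beta.data[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd, train = self._cache
        dbeta = dy.sum(axis=(0, 2, 3))
        dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dbeta
        self.gamma.grad += dgamma
        g = (self.gamma.data * invstd)[None, :, None, None]
        if not train:
            return dy * g
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        return g * (dy - dbeta[None, :, None, None] / n
                    - xhat * dgamma[None, :, None, None] / n)


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.01):
        self.negative_slope = negative_slope
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.negative_slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.negative_slope * dy)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SEBlock(Layer):
    """Squeeze-and-excitation channel attention.

    Squeeze: global average per channel.  Excite: a two-layer bottleneck
    (C -> C/ratio -> C) whose sigmoid output re-scales each channel by a
    weight in [0, 1].  Setting ``force_identity`` clamps every channel weight
    to 1, turning the block into an exact identity — used for the ablation
    comparison against the attention-free network.
    """

    def __init__(self, name: str, channels: int, ratio: int,
                 rng: np.random.Generator, negative_slope: float,
                 dtype=np.float32):
        if channels % ratio != 0:
            raise ValueError(
                f"SE ratio {ratio} must divide the channel count {channels}"
            )
        hidden = channels // ratio
        self.channels = channels
        self.negative_slope = negative_slope
        self.fc1_w = Param(f"{name}.fc1.weight",
                           kaiming_normal(rng, (hidden, channels), channels,
                                          negative_slope, dtype))
        self.fc1_b = Param(f"{name}.fc1.bias", np.zeros(hidden, dtype=dtype))
        self.fc2_w = Param(f"{name}.fc2.weight",
                           kaiming_normal(rng, (channels, hidden), hidden,
                                          negative_slope, dtype))
        self.fc2_b = Param(f"{name}.fc2.bias", np.zeros(channels, dtype=dtype))
        self.force_identity = False
        self._cache = None

    def params(self) -> list[Param]:
        return [self.fc1_w, self.fc1_b, self.fc2_w, self.fc2_b]

    def channel_weights(self, x: np.ndarray) -> np.ndarray:
        """The per-channel gate s in [0,1] for input x of shape (b,C,H,W)."""
        z = x.mean(axis=(2, 3))
        h_pre = z @ self.fc1_w.data.T + self.fc1_b.data
        h = np.where(h_pre >= 0, h_pre, self.negative_slope * h_pre)
        s_pre = h @ self.fc2_w.data.T + self.fc2_b.data
        return _sigmoid(s_pre)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.force_identity:
            self._cache = ("identity",)
            return x
        z = x.mean(axis=(2, 3))                       # (b, C)
        h_pre = z @ self.fc1_w.data.T + self.fc1_b.data
        hmask = h_pre >= 0
        h = np.where(hmask, h_pre, self.negative_slope * h_pre)
        s_pre = h @ self.fc2_w.data.T + self.fc2_b.data
        s = _sigmoid(s_pre)                           # (b, C)
        self._cache = ("se", x, z, hmask, h, s)
        return x * s[:, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache[0] == "identity":
            return dy
        _, x, z, hmask, h, s = self._cache
        hw = x.shape[2] * x.shape[3]
        dx = dy * s[:, :, None, None]
        ds = (dy * x).sum(axis=(2, 3))                # (b, C)
        dspre = ds * s * (1.0 - s)
        self.fc2_w.grad += dspre.T @ h
        self.fc2_b.grad += dspre.sum(axis=0)
        dh = dspre @ self.fc2_w.data
        dhpre = np.where(hmask, dh, self.negative_slope * dh)
        self.fc1_w.grad += dhpre.T @ z
        self.fc1_b.grad += dhpre.sum(axis=0)
        dz = dhpre @ self.fc1_w.data                  # (b, C)
        dx += dz[:, :, None, None] / hw
        return dx


class GlobalMaxPool(Layer):
    """Max over the spatial grid of every channel; output (b, C)."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        flat = x.reshape(b, c, h * w)
        idx = flat.argmax(axis=2)
        self._cache = (idx, (b, c, h, w))
        return np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (b, c, h, w) = self._cache
        dx = np.zeros((b, c, h * w), dtype=dy.dtype)
        np.put_along_axis(dx, idx[:, :, None], dy[:, :, None], axis=2)
        return dx.reshape(b, c, h, w)


class Linear(Layer):
    def __init__(self, name: str, in_features: int, out_features: int,
                 rng: np.random.Generator, negative_slope: float,
                 dtype=np.float32):
        self.weight = Param(f"{name}.weight",
                            kaiming_normal(rng, (out_features, in_features),
                                           in_features, negative_slope, dtype))
        self.bias = Param(f"{name}.bias", np.zeros(out_features, dtype=dtype))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._cache = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self.weight.grad += dy.T @ x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.data


class Adam:
    """Adam optimizer with bias correction and a constant learning rate."""

    def __init__(self, params: Iterable[Param], learning_rate: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
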