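"""Minimal NumPy neural-network engine for 1D convolutional regression.

Implements exactly the layer set needed by the joint-angle estimator —
1D convolution (bias-free), batch normalization, GELU, max pooling,
global average pooling, linear layers, dropout — together with reverse-mode
gradients, the Huber regression loss and the Adam optimizer.  Everything is
float32 and fully deterministic given a seed: initialization, dropout masks
and minibatch order all flow through explicit ``numpy.random.Generator``
instances.

The convolution is evaluated as a matrix product over an unfolded
(im2col) view; the backward pass scatters gradients back with a short
loop over the kernel taps, which is vectorized over batch, channel and
time and fast enough for desk-scale training on one CPU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

_F32 = np.float32
_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


@dataclass
class Param:
    """A trainable tensor with its accumulated gradient."""

    value: np.ndarray
    grad: np.ndarray = field(init=False)
    name: str = ""

    def __post_init__(self) -> None:
        self.value = np.ascontiguousarray(self.value, dtype=_F32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    """Base layer: forward caches what backward needs."""

    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _unfold(xp: np.ndarray, kernel: int, stride: int, l_out: int) -> np.ndarray:
    """(B, C, Lp) -> (B, C, kernel, l_out) by slicing per kernel tap."""
    b, c, _ = xp.shape
    cols = np.empty((b, c, kernel, l_out), dtype=xp.dtype)
    for j in range(kernel):
        cols[:, :, j, :] = xp[:, :, j : j + stride * (l_out - 1) + 1 : stride]
    return cols


def conv_out_len(l_in: int, kernel: int, stride: int, padding: int) -> int:
    """Temporal length after a 1D conv/pool: floor((L + 2p - k)/s) + 1."""
    return (l_in + 2 * padding - kernel) // stride + 1


class Conv1d(Layer):
    """Bias-free 1D convolution (cross-correlation), He-normal init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        rng = rng or np.random.default_rng()
        std = math.sqrt(2.0 / (in_ch * kernel))
        w = rng.normal(0.0, std, size=(out_ch, in_ch, kernel))
        self.weight = Param(w, name=f"conv{in_ch}x{out_ch}k{kernel}.weight")

    def parameters(self) -> list[Param]:
        return [self.weight]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != self.in_ch:
            raise ValueError(
                f"expected (B, {self.in_ch}, L) input, got {x.shape}")
        b, _, l_in = x.shape
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        l_out = conv_out_len(l_in, self.kernel, self.stride, p)
        if l_out < 1:
            raise ValueError("input too short for this convolution")
        cols = _unfold(xp, self.kernel, self.stride, l_out)
        cols2 = cols.reshape(b, self.in_ch * self.kernel, l_out)
        w2 = self.weight.value.reshape(self.out_ch, -1)
        out = np.matmul(w2, cols2)
        self._cache = (cols2, x.shape, l_out)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols2, x_shape, l_out = self._cache
        b, _, l_in = x_shape
        w2 = self.weight.value.reshape(self.out_ch, -1)
        dw = np.einsum("bol,bcl->oc", dy, cols2, optimize=True)
        self.weight.grad += dw.reshape(self.weight.value.shape)
        dcols2 = np.matmul(w2.T, dy)  # (B, C*k, l_out)
        dcols = dcols2.reshape(b, self.in_ch, self.kernel, l_out)
        p, s = self.padding, self.stride
        dxp = np.zeros((b, self.in_ch, l_in + 2 * p), dtype=_F32)
        for j in range(self.kernel):
            dxp[:, :, j : j + s * (l_out - 1) + 1 : s] += dcols[:, :, j, :]
        return dxp[:, :, p : p + l_in] if p else dxp


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, time)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.channels = channels
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(channels), name="bn.gamma")
        self.beta = Param(np.zeros(channels), name="bn.beta")
        self.running_mean = np.zeros(channels, dtype=_F32)
        self.running_var = np.ones(channels, dtype=_F32)

    def parameters(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(_F32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(_F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        self._cache = (xhat, inv_std, train, x.shape)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, train, shape = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma.value[None, :, None]
        if not train:
            return dxhat * inv_std[None, :, None]
        m = shape[0] * shape[2]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv_std[None, :, None] / m) * (m * dxhat - s1 - xhat * s2)


class GELU(Layer):
    """Exact Gaussian error linear unit, x * Phi(x)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cdf = 0.5 * (1.0 + erf(x / _SQRT2))
        self._cache = (x, cdf)
        return (x * cdf).astype(_F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, cdf = self._cache
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        return (dy * (cdf + x * pdf)).astype(_F32)


class MaxPool1d(Layer):
    def __init__(self, kernel: int, stride: int, padding: int = 0):
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, l_in = x.shape
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)), constant_values=-np.inf) if p else x
        l_out = conv_out_len(l_in, self.kernel, self.stride, p)
        cols = _unfold(xp, self.kernel, self.stride, l_out)
        arg = cols.argmax(axis=2)
        out = np.take_along_axis(cols, arg[:, :, None, :], axis=2)[:, :, 0, :]
        self._cache = (arg, x.shape, l_out)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        arg, x_shape, l_out = self._cache
        b, c, l_in = x_shape
        p, s = self.padding, self.stride
        dxp = np.zeros((b, c, l_in + 2 * p), dtype=_F32)
        for j in range(self.kernel):
            contrib = np.where(arg == j, dy, 0.0).astype(_F32)
            dxp[:, :, j : j + s * (l_out - 1) + 1 : s] += contrib
        return dxp[:, :, p : p + l_in] if p else dxp


class GlobalAvgPool1d(Layer):
    """(B, C, L) -> (B, C) by temporal mean."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._l = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, :, None], self._l, axis=2) / _F32(self._l)


class Linear(Layer):
    """Affine layer with bias; Kaiming-uniform init."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        self.in_features, self.out_features = in_features, out_features
        rng = rng or np.random.default_rng()
        bound = math.sqrt(6.0 / in_features)
        w = rng.uniform(-bound, bound, size=(out_features, in_features))
        b_bound = 1.0 / math.sqrt(in_features)
        b = rng.uniform(-b_bound, b_bound, size=out_features)
        self.weight = Param(w, name="linear.weight")
        self.bias = Param(b, name="linear.bias")

    def parameters(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_features:
            raise ValueError(
                f"expected {self.in_features} features, got {x.shape[1]}")
        self._cache = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self.weight.grad += dy.T @ x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(_F32) / _F32(keep)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def huber_loss(pred: np.ndarray, target: np.ndarray,
               delta: float = 1.0) -> tuple[float, np.ndarray]:
    """Mean Huber loss and its gradient w.r.t. predictions.

    Quadratic for residuals within ``delta``, linear beyond; the mean is
    taken over every element of the batch.
    """
    r = (pred - target).astype(np.float64)
    a = np.abs(r)
    quad = a <= delta
    loss = np.where(quad, 0.5 * r * r, delta * (a - 0.5 * delta))
    grad = np.where(quad, r, delta * np.sign(r)) / r.size
    return float(loss.mean()), grad.astype(_F32)


class Adam:
    """Adam optimizer with bias-corrected moment estimates."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad * p.grad
            p.value -= (self.lr / bc1) * m / (np.sqrt(v / bc2) + self.eps)
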