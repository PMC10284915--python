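"""Minimal CPU tensor layers (float32, NCHW) with hand-written backprop.

Only what the dual-encoder/dual-decoder translation network needs:
3x3 same-padding convolution, ReLU, batch normalization, 2x2 max pooling,
2x2 stride-2 transpose convolution, 1x1 convolution and a scaled tanh head.
Convolutions are realized as a small loop over kernel offsets, each a BLAS
tensordot, which keeps memory flat relative to im2col.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, stride 1, same padding (k odd)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator):
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_ch, in_ch, kernel, kernel))
        self.weight = Param(w)
        self.bias = Param(np.zeros(out_ch))
        self.kernel = kernel
        self.pad = kernel // 2
        self._xpad: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        p, k = self.pad, self.kernel
        B, C, H, W = x.shape
        xpad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        if training:
            self._xpad = xpad
        O = self.weight.value.shape[0]
        out = np.empty((B, H, W, O), dtype=DTYPE)
        out[:] = self.bias.value
        for di in range(k):
            for dj in range(k):
                xs = xpad[:, :, di:di + H, dj:dj + W]
                # (B,C,H,W) x (O,C) -> (B,H,W,O)
                out += np.tensordot(xs, self.weight.value[:, :, di, dj],
                                    axes=([1], [1]))
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        p, k = self.pad, self.kernel
        B, O, H, W = grad.shape
        xpad = self._xpad
        self._xpad = None
        g = grad  # (B,O,H,W)
        self.bias.grad += g.sum(axis=(0, 2, 3))
        dxpad = np.zeros_like(xpad)
        for di in range(k):
            for dj in range(k):
                xs = xpad[:, :, di:di + H, dj:dj + W]
                # dW: sum over batch+space of g (B,O,H,W) x xs (B,C,H,W)
                self.weight.grad[:, :, di, dj] += np.tensordot(
                    g, xs, axes=([0, 2, 3], [0, 2, 3]))
                # dx: g x W[:, :, di, dj] (O,C) -> (B,H,W,C)
                dxpad[:, :, di:di + H, dj:dj + W] += np.tensordot(
                    g, self.weight.value[:, :, di, dj],
                    axes=([1], [0])).transpose(0, 3, 1, 2)
        return dxpad[:, :, p:p + H, p:p + W] if p else dxpad


class ConvTranspose2d(Layer):
    """2x2 transpose convolution with stride 2 (doubles H and W)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        fan_in = in_ch * 4
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(in_ch, out_ch, 2, 2))
        self.weight = Param(w)
        self.bias = Param(np.zeros(out_ch))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        B, C, H, W = x.shape
        O = self.weight.value.shape[1]
        out = np.empty((B, O, 2 * H, 2 * W), dtype=DTYPE)
        for di in range(2):
            for dj in range(2):
                # (B,C,H,W) x (C,O) -> (B,H,W,O)
                v = np.tensordot(x, self.weight.value[:, :, di, dj],
                                 axes=([1], [0]))
                out[:, :, di::2, dj::2] = v.transpose(0, 3, 1, 2)
        out += self.bias.value[None, :, None, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        self._x = None
        self.bias.grad += grad.sum(axis=(0, 2, 3))
        dx = np.zeros_like(x)
        for di in range(2):
            for dj in range(2):
                g = grad[:, :, di::2, dj::2]  # (B,O,H,W)
                self.weight.grad[:, :, di, dj] += np.tensordot(
                    x, g, axes=([0, 2, 3], [0, 2, 3]))
                dx += np.tensordot(g, self.weight.value[:, :, di, dj],
                                   axes=([1], [1])).transpose(0, 3, 1, 2)
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad * self._mask
        self._mask = None
        return g


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if training:
            self._xhat, self._inv = xhat, inv
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None])

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self._xhat = None
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (g - gsum / n - xhat * gx / n) * inv[None, :, None, None]
        self._inv = None
        return dx.astype(DTYPE)


class MaxPool2d(Layer):
    """2x2, stride 2.  Ties share the gradient equally."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, C, H, W = x.shape
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(3, 5))
        if training:
            mask = (xr == out[:, :, :, None, :, None]).astype(DTYPE)
            mask /= mask.sum(axis=(3, 5), keepdims=True)
            self._mask = mask
            self._in_shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, H, W = self._in_shape
        g = grad[:, :, :, None, :, None] * self._mask
        self._mask = None
        return g.reshape(B, C, H, W)


class ScaledTanh(Layer):
    """y = scale * tanh(x); bounds the output to [-scale, scale]."""

    def __init__(self, scale: float = 5.0):
        self.scale = scale

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        t = np.tanh(x)
        if training:
            self._t = t
        return (self.scale * t).astype(DTYPE)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad * self.scale * (1.0 - self._t ** 2)
        self._t = None
        return g.astype(DTYPE)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
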