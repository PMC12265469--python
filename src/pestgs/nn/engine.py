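"""Layers, losses, and Adam for the damage-scoring convnets.

Conventions: activations are float32 NHWC; each layer caches what its own
backward pass needs; gradient buffers are persistent arrays written in
place so the optimiser can hold references. Dropout and any other stochastic
behaviour draw from the generator passed to ``forward``, never from global
state.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_F32 = np.float32


class Layer:
    frozen = False

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(param, grad-buffer) pairs; empty for stateless layers."""
        return []


class Conv2D(Layer):
    """'Same'-padded k x k convolution, stride 1, He-normal init."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int = 3, rng=None):
        rng = rng or np.random.default_rng()
        fan_in = ksize * ksize * in_ch
        self.k = ksize
        self.in_ch, self.out_ch = in_ch, out_ch
        self.W = (rng.standard_normal((fan_in, out_ch)) * np.sqrt(2.0 / fan_in)).astype(_F32)
        self.b = np.zeros(out_ch, dtype=_F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._shape = None

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {c}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))  # n,h,w,c,k,k
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * h * w, self.k * self.k * c
        )
        out = cols @ self.W + self.b
        self._cols, self._shape = cols, (n, h, w, c)
        return out.reshape(n, h, w, self.out_ch)

    def backward(self, grad):
        n, h, w, c = self._shape
        g2 = grad.reshape(n * h * w, self.out_ch).astype(_F32)
        self.dW[...] = self._cols.T @ g2
        self.db[...] = g2.sum(axis=0)
        dcols = (g2 @ self.W.T).reshape(n, h, w, self.k, self.k, c)
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=_F32)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        self._cols = None
        return dxp[:, p : p + h, p : p + w, :]

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0)


class MaxPool2D(Layer):
    """2x2 max pooling; spatial dims must be even."""

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        xr = (
            x.reshape(n, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, h // 2, w // 2, 4, c)
        )
        self._idx = xr.argmax(axis=3)
        self._shape = (n, h, w, c)
        return np.take_along_axis(xr, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, grad):
        n, h, w, c = self._shape
        dxr = np.zeros((n, h // 2, w // 2, 4, c), dtype=_F32)
        np.put_along_axis(dxr, self._idx[:, :, :, None, :], grad[:, :, :, None, :], axis=3)
        return (
            dxr.reshape(n, h // 2, w // 2, 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, h, w, c)
        )


class GAP(Layer):
    """Global average pooling: NHWC -> N x C."""

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        n, h, w, c = self._shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w), self._shape).astype(_F32)


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng=None):
        rng = rng or np.random.default_rng()
        self.W = (rng.standard_normal((in_dim, out_dim)) * np.sqrt(2.0 / in_dim)).astype(_F32)
        self.b = np.zeros(out_dim, dtype=_F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        grad = grad.astype(_F32)
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Dropout(Layer):
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs a random generator")
        self._mask = (rng.random(x.shape) >= self.rate).astype(_F32) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class ScaledSigmoid(Layer):
    """sigmoid(z) * scale — bounds the regression head to [0, scale]."""

    def __init__(self, scale: float = 1.0):
        self.scale = scale

    def forward(self, x, train=False, rng=None):
        s = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        self._s = s
        return (self.scale * s).astype(_F32)

    def backward(self, grad):
        return (grad * self.scale * self._s * (1.0 - self._s)).astype(_F32)


class Residual(Layer):
    """Two-conv residual block with optional 1x1 projection on the skip path."""

    def __init__(self, in_ch: int, out_ch: int, rng=None):
        rng = rng or np.random.default_rng()
        self.body = [Conv2D(in_ch, out_ch, 3, rng), ReLU(), Conv2D(out_ch, out_ch, 3, rng)]
        self.proj = Conv2D(in_ch, out_ch, 1, rng) if in_ch != out_ch else None

    def forward(self, x, train=False, rng=None):
        y = x
        for layer in self.body:
            y = layer.forward(y, train, rng)
        s = self.proj.forward(x, train, rng) if self.proj is not None else x
        z = y + s
        self._mask = z > 0
        return np.where(self._mask, z, 0)

    def backward(self, grad):
        dz = np.where(self._mask, grad, 0).astype(_F32)
        dy = dz
        for layer in reversed(self.body):
            dy = layer.backward(dy)
        ds = self.proj.backward(dz) if self.proj is not None else dz
        return dy + ds

    def parameters(self):
        out = []
        for layer in self.body:
            out.extend(layer.parameters())
        if self.proj is not None:
            out.extend(self.proj.parameters())
        return out


class Sequential:
    """An ordered layer stack with forward/backward and weight (de)serialisation."""

    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self, trainable_only: bool = False):
        out = []
        for layer in self.layers:
            if trainable_only and layer.frozen:
                continue
            out.extend(layer.parameters())
        return out

    def n_params(self) -> int:
        return int(sum(p.size for p, _ in self.parameters()))

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = [
            self.forward(x[i : i + batch_size].astype(_F32))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list does not match parameter count")
        for (p, _), w in zip(params, weights):
            p[...] = w

    def save_weights(self, path: str) -> None:
        np.savez(path, *[p for p, _ in self.parameters()])

    def load_weights(self, path: str) -> None:
        with np.load(path) as data:
            self.set_weights([data[k] for k in data.files])


class Adam:
    """Adam with bias correction; updates the (param, grad) pairs it was given."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(diff**2)), (2.0 * diff / diff.size).astype(_F32)


def bce_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    eps = 1e-7
    p = np.clip(pred, eps, 1.0 - eps)
    loss = float(-np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))
    grad = ((p - target) / (p * (1.0 - p)) / p.size).astype(_F32)
    return loss, grad
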