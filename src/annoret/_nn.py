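"""Minimal deterministic neural-net primitives (numpy, CPU, single thread).

Implements just what the VOI classifiers need: 2D/3D convolutions with
'same' padding, max-pooling, dense layers, ReLU, a residual block, binary
cross-entropy on logits, and momentum SGD with weight decay.  All
randomness flows through an explicit Generator, so training is bit-stable
for a fixed seed.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

__all__ = [
    "Dense",
    "ReLU",
    "Flatten",
    "ConvND",
    "MaxPoolND",
    "ResidualBlock",
    "Sequential",
    "MomentumSGD",
    "bce_with_logits",
]


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(parameter, gradient) pairs; gradients filled by backward()."""
        return []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class ConvND(Layer):
    """k^nd convolution with 'same' (zero) padding, stride 1.

    Input layout (N, C, *spatial); nd is 2 or 3; kernel size must be odd.
    """

    def __init__(self, nd: int, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.nd = nd
        self.k = k
        fan_in = c_in * k**nd
        self.w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(c_out, c_in) + (k,) * nd)
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        pad = self.k // 2
        pads = [(0, 0), (0, 0)] + [(pad, pad)] * self.nd
        xp = np.pad(x, pads)
        self._xp = xp
        axes = tuple(range(2, 2 + self.nd))
        view = sliding_window_view(xp, (self.k,) * self.nd, axis=axes)
        self._view = view
        if self.nd == 3:
            out = np.einsum("ncdhwijk,ocijk->nodhw", view, self.w, optimize=True)
        else:
            out = np.einsum("nchwij,ocij->nohw", view, self.w, optimize=True)
        out += self.b.reshape((1, -1) + (1,) * self.nd)
        return out

    def backward(self, grad):
        if self.nd == 3:
            self.dw[...] = np.einsum(
                "nodhw,ncdhwijk->ocijk", grad, self._view, optimize=True
            )
        else:
            self.dw[...] = np.einsum("nohw,nchwij->ocij", grad, self._view, optimize=True)
        self.db[...] = grad.sum(axis=(0,) + tuple(range(2, 2 + self.nd)))
        gx_p = np.zeros_like(self._xp)
        spatial = grad.shape[2:]
        for offs in itertools.product(range(self.k), repeat=self.nd):
            w_o = self.w[(slice(None), slice(None)) + offs]  # (c_out, c_in)
            contrib = np.einsum("no...,oc->nc...", grad, w_o, optimize=True)
            slices = tuple(
                slice(o, o + s) for o, s in zip(offs, spatial)
            )
            gx_p[(slice(None), slice(None)) + slices] += contrib
        pad = self.k // 2
        crop = tuple(slice(pad, d - pad) for d in gx_p.shape[2:])
        return gx_p[(slice(None), slice(None)) + crop]

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class MaxPoolND(Layer):
    """Non-overlapping factor-2 max pooling; spatial dims must be even."""

    def __init__(self, nd: int):
        self.nd = nd

    def forward(self, x):
        if any(d % 2 for d in x.shape[2:]):
            raise ValueError(f"spatial dims must be even for 2x pooling, got {x.shape}")
        shape = x.shape[:2]
        new = []
        for d in x.shape[2:]:
            new.extend([d // 2, 2])
        xr = x.reshape(shape + tuple(new))
        axes = tuple(3 + 2 * i for i in range(self.nd))
        out = xr.max(axis=axes, keepdims=True)
        mask = (xr == out)
        # split gradient across ties to keep backward deterministic
        self._mask = mask / mask.sum(axis=axes, keepdims=True)
        self._in_shape = x.shape
        self._axes = axes
        return out.squeeze(axis=axes)

    def backward(self, grad):
        g = np.expand_dims(grad, self._axes)
        return (g * self._mask).reshape(self._in_shape)


class ResidualBlock(Layer):
    """x -> relu(x + conv(relu(conv(x)))), channel-preserving."""

    def __init__(self, nd: int, channels: int, k: int, rng: np.random.Generator):
        self.conv1 = ConvND(nd, channels, channels, k, rng)
        self.relu1 = ReLU()
        self.conv2 = ConvND(nd, channels, channels, k, rng)
        self.relu_out = ReLU()

    def forward(self, x):
        y = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        return self.relu_out.forward(x + y)

    def backward(self, grad):
        g = self.relu_out.backward(grad)
        g_branch = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        return g + g_branch

    def params(self):
        return self.conv1.params() + self.conv2.params()


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def predict_logits(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        out = [
            self.forward(x[i : i + batch]).reshape(-1)
            for i in range(0, len(x), batch)
        ]
        return np.concatenate(out) if out else np.empty(0)


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    z = logits.reshape(-1)
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    grad = (expit(z) - y) / len(z)
    return loss, grad


class MomentumSGD:
    def __init__(
        self,
        params: Sequence[tuple[np.ndarray, np.ndarray]],
        lr: float,
        momentum: float = 0.99,
        weight_decay: float = 0.001,
    ):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p) for p, _ in self.params]

    def step(self) -> None:
        for v, (p, g) in zip(self.velocity, self.params):
            v *= self.momentum
            v -= self.lr * (g + self.weight_decay * p)
            p += v
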