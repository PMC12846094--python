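"""Minimal NumPy neural-network layers for the scratch convolutional classifier.

Only what the scratch backbone + dense head needs: 3x3 same-padding
convolution, ReLU, 2x2 max pooling, global average pooling, dense layers,
inverted dropout and a softmax cross-entropy loss, trained with Adam.
Channels-last layout (N, H, W, C) throughout; float32.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 convolution, stride 1, zero 'same' padding, He-initialised."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        scale = np.sqrt(2.0 / (k * k * c_in))
        self.k = k
        self.W = (rng.standard_normal((k, k, c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x, train):
        n, h, w, _ = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp = xp
        out = np.broadcast_to(self.b, (n, h, w, self.W.shape[3])).copy()
        for di in range(self.k):
            for dj in range(self.k):
                patch = xp[:, di : di + h, dj : dj + w, :]
                out += patch @ self.W[di, dj]
        return out

    def backward(self, g):
        xp = self._xp
        n, h, w, _ = g.shape
        p = self.k // 2
        gxp = np.zeros_like(xp)
        self.gb[...] = g.sum(axis=(0, 1, 2))
        g2 = g.reshape(-1, g.shape[3])
        for di in range(self.k):
            for dj in range(self.k):
                patch = xp[:, di : di + h, dj : dj + w, :]
                self.gW[di, dj] = patch.reshape(-1, patch.shape[3]).T @ g2
                gxp[:, di : di + h, dj : dj + w, :] += g @ self.W[di, dj].T
        return gxp[:, p : p + h, p : p + w, :]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class MaxPool2(Layer):
    """2x2 max pooling; tie gradients split evenly (ties are measure-zero in practice)."""

    def forward(self, x, train):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        mask = (xr == out[:, :, None, :, None, :]).astype(np.float32)
        mask /= np.maximum(mask.sum(axis=(2, 4), keepdims=True), 1.0)
        self._mask = mask
        self._shape = x.shape
        return out

    def backward(self, g):
        n, h, w, c = self._shape
        gx = self._mask * g[:, :, None, :, None, :]
        return gx.reshape(n, h, w, c)


class GlobalAveragePool(Layer):
    def forward(self, x, train):
        self._hw = x.shape[1] * x.shape[2]
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, g):
        n, h, w, c = self._shape
        return np.broadcast_to(g[:, None, None, :] / self._hw, (n, h, w, c)).copy()


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.gW[...] = self._x.T @ g
        self.gb[...] = g.sum(axis=0)
        return g @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, g):
        if self._mask is None:
            return g
        return g * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and gradient w.r.t. logits; y holds class indices."""
    n = len(y)
    p = softmax(logits)
    loss = float(-np.mean(np.log(p[np.arange(n), y] + 1e-12)))
    g = p.copy()
    g[np.arange(n), y] -= 1.0
    return loss, (g / n).astype(np.float32)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def n_params(self) -> int:
        return sum(p.size for p in self.params())


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 0.002,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
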