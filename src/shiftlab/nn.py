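"""Minimal NumPy neural-network core used by the VAE and the translator.

Layers operate on NCHW float32 arrays and implement explicit forward/backward
passes (im2col convolutions, nearest-neighbour upsampling, dense layers).
Everything is deterministic given a seeded ``numpy.random.Generator`` and a
fixed thread configuration, which is what makes seeded training reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "Dense",
    "LeakyReLU",
    "Sigmoid",
    "Upsample2x",
    "Adam",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N,C,H,W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, k, k, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
    )
    return np.ascontiguousarray(cols).reshape(n, c * k * k, ho * wo), (ho, wo)


def _col2im(dcols: np.ndarray, xshape, k: int, stride: int, pad: int):
    """Adjoint of _im2col: scatter-add patch gradients back to image."""
    n, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    dx = np.zeros((n, c, hp, wp), dtype=np.float32)
    dcols = dcols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += dcols[:, :, i, j]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class Layer:
    """Base: parameters/grads are parallel lists of arrays."""

    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.k, self.stride = k, stride
        self.pad = k // 2 if pad is None else pad
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init for leaky-relu nets
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, k, k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        cols, (ho, wo) = _im2col(x, self.k, self.stride, self.pad)
        self._cache = (x.shape, cols)
        c_out = self.w.shape[0]
        out = self.w.reshape(c_out, -1) @ cols  # (N, c_out, Ho*Wo) batched
        out = out + self.b[:, None]
        return out.reshape(x.shape[0], c_out, ho, wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xshape, cols = self._cache
        n, c_out = dy.shape[:2]
        dyf = np.ascontiguousarray(dy, dtype=np.float32).reshape(n, c_out, -1)
        wf = self.w.reshape(c_out, -1)
        self.grads[0][...] = (dyf @ cols.transpose(0, 2, 1)).sum(axis=0).reshape(self.w.shape)
        self.grads[1][...] = dyf.sum(axis=(0, 2))
        dcols = np.matmul(wf.T, dyf)
        self._cache = None
        return _col2im(dcols, xshape, self.k, self.stride, self.pad)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / d_in)
        self.w = rng.normal(0.0, scale, size=(d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        dx = dy @ self.w.T
        self._x = None
        return dx


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        super().__init__()
        self.alpha = alpha

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.alpha * dy)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = sigmoid(x)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Upsample2x(Layer):
    """Nearest-neighbour 2x upsampling; backward sums 2x2 blocks."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = dy.shape
        return dy.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


class Adam:
    """Adam over a flat list of (param, grad) array pairs."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.pairs = []
        for layer in layers:
            self.pairs.extend(zip(layer.params, layer.grads))
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self):
        for _, g in self.pairs:
            g[...] = 0.0
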