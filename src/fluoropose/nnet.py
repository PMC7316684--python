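"""Minimal deterministic NumPy neural-network layers.

Only what the landmark regressor needs: 3x3 "same" convolutions (im2col +
BLAS matmul), ReLU, 2x2 max/average pooling, fully connected layers, inverted
dropout, mean-squared-error loss and Adam.  Arrays are NHWC float32; all
randomness flows through explicitly passed ``numpy.random.Generator``
instances, so two builds/runs from the same seed are bit-identical.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "Pool2D",
    "Flatten",
    "Dense",
    "Dropout",
    "Sequential",
    "Adam",
    "mse_loss",
]


class Layer:
    """Base layer: forward caches whatever backward needs."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool, rng) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 same-padding convolution, He-initialized.

    Forward builds an im2col matrix in (tap-row, tap-col, channel) order —
    the channel axis stays memory-contiguous, which keeps the gather fast —
    and the matrix is reused by the weight-gradient GEMM.  The input
    gradient is accumulated tap-by-tap from the padded output gradient,
    avoiding a second large gather.  Weights are stored (k, k, C_in, C_out);
    ``is_input_layer`` skips the (unused) input gradient of the first layer.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        super().__init__()
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.is_input_layer = False
        std = math.sqrt(2.0 / (k * k * c_in))
        w = rng.normal(0.0, std, size=(k, k, c_in, c_out)).astype(np.float32)
        b = np.zeros(c_out, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def _cols(self, x: np.ndarray) -> np.ndarray:
        n, h, w_, c = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k),
                                                       axis=(1, 2))
        win = win.transpose(0, 1, 2, 4, 5, 3)  # (N, H, W, k, k, C)
        return np.ascontiguousarray(win).reshape(n * h * w_,
                                                 self.k * self.k * c)

    def forward(self, x, training, rng):
        n, h, w_, _ = x.shape
        self._shape = x.shape
        cols = self._cols(x)
        self._cols_cache = cols if training else None
        y = cols @ self.params[0].reshape(-1, self.c_out) + self.params[1]
        return y.reshape(n, h, w_, self.c_out)

    def backward(self, dy):
        n, h, w_, _ = self._shape
        p = self.k // 2
        dyf = dy.reshape(-1, self.c_out)
        self.grads[0][...] = (self._cols_cache.T @ dyf).reshape(self.grads[0].shape)
        self.grads[1][...] = dyf.sum(axis=0)
        self._cols_cache = None
        if self.is_input_layer:
            return None
        # input gradient: full correlation of dy with the flipped kernel,
        # accumulated per tap so only small contiguous copies are made
        dyp = np.pad(dy, ((0, 0), (p, p), (p, p), (0, 0)))
        dx = np.zeros((n * h * w_, self.c_in), dtype=np.float32)
        wmat = self.params[0]
        for di in range(self.k):
            for dj in range(self.k):
                tap = np.ascontiguousarray(
                    dyp[:, di : di + h, dj : dj + w_]).reshape(-1, self.c_out)
                dx += tap @ wmat[self.k - 1 - di, self.k - 1 - dj].T
        return dx.reshape(n, h, w_, self.c_in)


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return np.maximum(x, 0.0, out=x)  # conv output is not reused

    def backward(self, dy):
        return np.multiply(dy, self._mask, out=dy)


class Pool2D(Layer):
    """2x2 max or average pooling with stride 2; odd trailing rows/cols drop."""

    def __init__(self, kind: str = "average"):
        super().__init__()
        if kind not in ("max", "average"):
            raise ValueError(f"unknown pooling kind {kind!r}")
        self.kind = kind

    def forward(self, x, training, rng):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xc = x[:, : 2 * h2, : 2 * w2]
        blocks = xc.reshape(n, h2, 2, w2, 2, c)
        if self.kind == "average":
            return blocks.mean(axis=(2, 4))
        flat = blocks.transpose(0, 1, 3, 2, 4, 5).reshape(n, h2, w2, 4, c)
        self._argmax = flat.argmax(axis=3)
        return flat.max(axis=3)

    def backward(self, dy):
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        dx = np.zeros((n, h, w, c), dtype=dy.dtype)
        if self.kind == "average":
            up = np.empty((n, h2, 2, w2, 2, c), dtype=dy.dtype)
            up[...] = 0.25 * dy[:, :, None, :, None, :]
            dx[:, : 2 * h2, : 2 * w2] = up.reshape(n, 2 * h2, 2 * w2, c)
            return dx
        flat = np.zeros((n, h2, w2, 4, c), dtype=dy.dtype)
        np.put_along_axis(flat, self._argmax[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        blocks = flat.reshape(n, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        dx[:, : 2 * h2, : 2 * w2] = blocks.reshape(n, 2 * h2, 2 * w2, c)
        return dx


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        std = math.sqrt(2.0 / n_in)
        w = rng.normal(0.0, std, size=(n_in, n_out)).astype(np.float32)
        b = np.zeros(n_out, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        self._x = None
        return dy @ self.params[0].T


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential:
    """Plain layer stack with explicit forward/backward passes."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, training, rng)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        grad = dy
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w

    @property
    def n_weight_layers(self) -> int:
        return sum(1 for layer in self.layers if layer.params)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all entries and its gradient w.r.t. pred."""
    diff = (pred - target).astype(np.float32)
    loss = float(np.mean(diff**2))
    return loss, (2.0 / diff.size) * diff


class Adam:
    """Adam with standard parameters (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[np.ndarray], lr: float = 5e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = b1 * m + (1.0 - b1) * g
            v[...] = b2 * v + (1.0 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


class SGDNesterov:
    """SGD with Nesterov momentum (the alternative optimizer evaluated)."""

    def __init__(self, params: list[np.ndarray], lr: float = 5e-3,
                 momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.vel = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        mu = self.momentum
        for p, g, v in zip(self.params, grads, self.vel, strict=True):
            v_prev = v.copy()
            v[...] = mu * v - self.lr * g
            p += -mu * v_prev + (1.0 + mu) * v
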