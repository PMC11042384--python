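"""Minimal NumPy neural-network primitives used by the sequence CNN.

Layers store their parameters and, after a backward pass, the matching
gradients. Shapes: sequence inputs are (N, C, L) with C channels (4 bases)
and L positions (20); convolution outputs are kept length-major as
(N, L_out, F) so flattening is a plain reshape.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv1d(Layer):
    """Valid-padding 1-D convolution over the position axis."""

    def __init__(self, in_channels: int, filters: int, kernel: int, stride: int = 1, rng=None):
        self.kernel = kernel
        self.stride = stride
        self.in_channels = in_channels
        self.filters = filters
        rng = np.random.default_rng(rng)
        fan_in = in_channels * kernel
        # He initialization, appropriate for the ReLU that follows
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(filters, in_channels * kernel))
        self.b = np.zeros(filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @staticmethod
    def out_length(length: int, kernel: int, stride: int) -> int:
        return (length - kernel) // stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        k, s = self.kernel, self.stride
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)[:, :, ::s, :]
        # (N, C, Lout, k) -> (N, Lout, C*k)
        self._cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(n, -1, c * k)
        self._in_shape = x.shape
        return self._cols @ self.W.T + self.b

    def backward(self, dy: np.ndarray, input_only: bool = False) -> np.ndarray:
        n, c, length = self._in_shape
        k, s = self.kernel, self.stride
        if not input_only:
            f = self.filters
            self.dW[...] = dy.reshape(-1, f).T @ self._cols.reshape(-1, c * k)
            self.db[...] = dy.sum(axis=(0, 1))
        dcols = dy @ self.W  # (N, Lout, C*k)
        dx = np.zeros(self._in_shape)
        for i in range(dcols.shape[1]):
            dx[:, :, i * s : i * s + k] += dcols[:, i].reshape(n, c, k)
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng=None):
        rng = np.random.default_rng(rng)
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray, input_only: bool = False) -> np.ndarray:
        if not input_only:
            self.dW[...] = self._x.T @ dy
            self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1d(Layer):
    """Max pooling over the length axis of (N, L, F); L must divide by size."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, length, f = x.shape
        if length % self.size:
            raise ValueError(f"pool size {self.size} does not divide length {length}")
        blocks = x.reshape(n, length // self.size, self.size, f)
        if self.size == 2:
            # first-element-wins tie-break, matching argmax
            self._first_wins = blocks[:, :, 0, :] >= blocks[:, :, 1, :]
            self._argmax = None
            out = np.where(self._first_wins, blocks[:, :, 0, :], blocks[:, :, 1, :])
        else:
            self._argmax = blocks.argmax(axis=2)
            out = np.take_along_axis(blocks, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]
        self._in_shape = x.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, lout, f = dy.shape
        dx = np.zeros((n, lout, self.size, f))
        if self._argmax is None:
            dx[:, :, 0, :] = dy * self._first_wins
            dx[:, :, 1, :] = dy * ~self._first_wins
        else:
            idx_n, idx_l, idx_f = np.ogrid[:n, :lout, :f]
            dx[idx_n, idx_l, self._argmax, idx_f] = dy
        return dx.reshape(self._in_shape)


class Dropout(Layer):
    """Inverted dropout; identity when no RNG is supplied (evaluation mode)."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        if rng is None or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    n = logits.shape[0]
    loss = float(np.mean(np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))))
    grad = (sigmoid(logits) - y) / n
    return loss, grad


def mse_loss(pred: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    n = pred.shape[0]
    diff = pred - y
    return float(np.mean(diff ** 2)), 2.0 * diff / n
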