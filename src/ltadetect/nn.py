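"""Minimal 1-D CNN engine: layers, manual backprop, Adam.

The package trains a residual convolutional network on a single CPU, so
the engine is written directly on numpy: activations are float32 arrays of
shape ``(N, L, C)`` (batch, time, channels), convolutions are im2col
matrix multiplications against BLAS, and every layer implements an exact
analytic backward pass.  Temporal subsampling is done by 2-sample max
pooling at block inputs, so all convolutions run with stride 1 ("same"
padding; even kernels pad ``k//2 - 1`` left, ``k//2`` right).

Layers expose ``params()`` as ``Param`` objects (value + grad + trainable
flag); freezing a layer both stops its updates and, for batch
normalization, switches it to stored running statistics so frozen blocks
are bit-immutable during further training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Param",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "Dropout",
    "MaxPool1d",
    "TimeDistributedDense",
    "Adam",
]


@dataclass
class Param:
    name: str
    value: np.ndarray
    grad: np.ndarray = field(default=None, repr=False)
    trainable: bool = True

    def __post_init__(self) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _tap_conv(xpad: np.ndarray, w: np.ndarray, L: int) -> np.ndarray:
    """sum_j xpad[:, j:j+L, :] @ w[j] without materializing im2col patches.

    Strided batched matmul per kernel tap is the fastest correlation
    strategy here (memory-bound im2col copies dominate otherwise).
    """
    y = xpad[:, 0:L, :] @ w[0]
    for j in range(1, len(w)):
        y += xpad[:, j : j + L, :] @ w[j]
    return y


class Layer:
    trainable = True

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padding stride-1 convolution; weight shape (k, cin, cout)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, name: str):
        std = np.sqrt(2.0 / (k * cin))
        w = rng.normal(0.0, std, size=(k, cin, cout)).astype(np.float32)
        self.w = Param(f"{name}.w", w)
        self.b = Param(f"{name}.b", np.zeros(cout, dtype=np.float32))
        self.cin, self.cout, self.k = cin, cout, k
        self.pl, self.pr = k // 2 - 1, k // 2  # even kernels: asymmetric
        if k % 2:
            self.pl = self.pr = k // 2
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        n, L, _ = x.shape
        xpad = np.pad(x, ((0, 0), (self.pl, self.pr), (0, 0)))
        return _tap_conv(xpad, self.w.value, L) + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n, L, _ = dy.shape
        xpad = np.pad(x, ((0, 0), (self.pl, self.pr), (0, 0)))
        if self.w.trainable:
            for j in range(self.k):
                self.w.grad[j] += np.matmul(
                    xpad[:, j : j + L, :].transpose(0, 2, 1), dy
                ).sum(axis=0)
            self.b.grad += dy.sum(axis=(0, 1))
        # data gradient: full correlation with the flipped, transposed kernel
        wf = self.w.value[::-1].transpose(0, 2, 1)  # (k, cout, cin)
        dypad = np.pad(dy, ((0, 0), (self.pr, self.pl), (0, 0)))
        dx = _tap_conv(dypad, wf, L)
        self._x = None
        return dx


class BatchNorm1d(Layer):
    """Batch normalization over (batch, time) per channel.

    A *frozen* layer uses its stored running statistics even in training
    mode and never updates them, preserving bit-immutability.
    """

    def __init__(self, c: int, name: str, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(f"{name}.gamma", np.ones(c, dtype=np.float32))
        self.beta = Param(f"{name}.beta", np.zeros(c, dtype=np.float32))
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.frozen = False
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def state(self) -> dict[str, np.ndarray]:
        return {"run_mean": self.run_mean, "run_var": self.run_var}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training and not self.frozen:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.run_mean += self.momentum * (mean - self.run_mean)
            self.run_var += self.momentum * (var - self.run_var)
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if training:
            self._cache = (xhat, inv.astype(np.float32), not self.frozen)
        return (self.gamma.value * xhat + self.beta.value).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, batch_stats = self._cache
        self._cache = None
        if self.gamma.trainable:
            self.gamma.grad += (dy * xhat).sum(axis=(0, 1))
            self.beta.grad += dy.sum(axis=(0, 1))
        g = dy * self.gamma.value
        if not batch_stats:
            return (g * inv).astype(np.float32)
        m = dy.shape[0] * dy.shape[1]
        dxhat_sum = g.sum(axis=(0, 1))
        dxhat_dot = (g * xhat).sum(axis=(0, 1))
        dx = inv * (g - dxhat_sum / m - xhat * (dxhat_dot / m))
        return dx.astype(np.float32)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p, self.rng = p, rng
        self._mask = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool1d(Layer):
    """Non-overlapping 2-sample max pooling along time (ties -> first)."""

    def __init__(self) -> None:
        self._sel = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, L, c = x.shape
        if L % 2:
            raise ValueError("max pooling requires even length")
        a, b = x[:, 0::2], x[:, 1::2]
        take_b = b > a
        if training:
            self._sel = take_b
        return np.where(take_b, b, a)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        take_b = self._sel
        self._sel = None
        n, L2, c = dy.shape
        dx = np.zeros((n, L2 * 2, c), dtype=dy.dtype)
        dx[:, 0::2] = np.where(take_b, 0.0, dy)
        dx[:, 1::2] = np.where(take_b, dy, 0.0)
        return dx


class TimeDistributedDense(Layer):
    """Shared-weight fully connected layer applied to every time step."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str):
        lim = np.sqrt(6.0 / (cin + cout))
        self.w = Param(f"{name}.w", rng.uniform(-lim, lim, size=(cin, cout)).astype(np.float32))
        self.b = Param(f"{name}.b", np.zeros(cout, dtype=np.float32))
        self._x = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self._x = None
        n, L, cin = x.shape
        if self.w.trainable:
            self.w.grad += x.reshape(n * L, cin).T @ dy.reshape(n * L, -1)
            self.b.grad += dy.sum(axis=(0, 1))
        return dy @ self.w.value.T


class Adam:
    """Adam with per-parameter state; frozen parameters are never touched."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {p.name: np.zeros_like(p.value) for p in params}
        self.v = {p.name: np.zeros_like(p.value) for p in params}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p in self.params:
            if not p.trainable:
                continue
            m = self.m[p.name]
            v = self.v[p.name]
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad**2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
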