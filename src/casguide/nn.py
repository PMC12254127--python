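"""Minimal NumPy neural-network primitives with manual backpropagation.

Provides exactly the pieces the activity model needs: same-padding 1-D
convolutions (via an im2col matmul), dense layers, sigmoid/ReLU
activations, global max pooling, the Adam optimizer, and a cosine
annealing schedule with warm restarts.  Layers are functional: ``forward``
returns ``(output, cache)`` and ``backward(cache, grad)`` returns the
input gradient while accumulating parameter gradients, so one layer
instance can be applied to several inputs (e.g. one protein per variant)
within a single step.

All arithmetic is float32.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable

import numpy as np

F32 = np.float32


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def sigmoid(x: np.ndarray) -> np.ndarray:
    # Pre-activation clip at +-15 keeps outputs strictly inside (0, 1) in
    # float32 (sigmoid(15) = 1 - 3.1e-7), so the derivative y*(1-y) is never
    # exactly zero and a saturated unit (notably the fusion gate) remains
    # recoverable by the optimizer.
    return 1.0 / (1.0 + np.exp(-np.clip(x, -15.0, 15.0)))


_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    # name -> (f, f' expressed in terms of the output y)
    "sigmoid": (sigmoid, lambda y: y * (1.0 - y)),
    "relu": (lambda x: np.maximum(x, 0.0), lambda y: (y > 0.0).astype(F32)),
    "linear": (lambda x: x, lambda y: np.ones_like(y)),
}


# Activation-dependent init gains.  Sigmoid contracts signal by its slope
# (1/4 near zero); without the classic 4x compensation a deep sigmoid stack
# collapses inter-sample variation geometrically and training stalls.
_INIT_GAINS = {"sigmoid": 4.0, "relu": math.sqrt(2.0), "linear": 1.0}


def uniform_fan_in(rng: np.random.Generator, fan_in: int,
                   shape: tuple[int, ...], activation: str) -> np.ndarray:
    """Uniform fan-in (LeCun-style) initialization with activation gain."""
    limit = _INIT_GAINS[activation] * math.sqrt(3.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Dense:
    """Fully connected layer ``y = act(x @ W + b)``."""

    def __init__(self, n_in: int, n_out: int, activation: str, rng: np.random.Generator):
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.W = Param(uniform_fan_in(rng, n_in, (n_in, n_out), activation))
        self.b = Param(np.zeros(n_out, dtype=F32))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray):
        z = x @ self.W.value + self.b.value
        y = _ACTIVATIONS[self.activation][0](z)
        return y, (x, y)

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        x, y = cache
        dz = dy * _ACTIVATIONS[self.activation][1](y)
        self.W.grad += x.T @ dz
        self.b.grad += dz.sum(axis=0)
        return dz @ self.W.value.T


class Conv1d:
    """Same-padding 1-D convolution over (batch, length, channels) input.

    Output length equals input length for odd kernels with
    padding = (kernel_size - 1) / 2, which is the only mode used here.
    """

    def __init__(self, channels_in: int, channels_out: int, kernel_size: int,
                 activation: str, rng: np.random.Generator, padding: int | None = None):
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd for same-length output")
        self.kernel_size = kernel_size
        self.padding = (kernel_size - 1) // 2 if padding is None else padding
        self.channels_in = channels_in
        self.channels_out = channels_out
        self.activation = activation
        fan_in = kernel_size * channels_in
        self.W = Param(uniform_fan_in(rng, fan_in, (fan_in, channels_out),
                                      activation))
        self.b = Param(np.zeros(channels_out, dtype=F32))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _im2col(self, xp: np.ndarray, out_len: int) -> np.ndarray:
        b, _, c = xp.shape
        k = self.kernel_size
        cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        # (b, out_len, c, k) -> (b, out_len, k*c) matching W's (k*c, out) layout
        cols = cols.transpose(0, 1, 3, 2).reshape(b, out_len, k * c)
        return np.ascontiguousarray(cols)

    def forward(self, x: np.ndarray, need_input_grad: bool = True):
        b, length, c = x.shape
        if c != self.channels_in:
            raise ValueError(f"expected {self.channels_in} input channels, got {c}")
        p = self.padding
        xp = np.pad(x, ((0, 0), (p, p), (0, 0))) if p else x
        out_len = length + 2 * p - self.kernel_size + 1
        cols = self._im2col(xp, out_len)
        z = cols.reshape(b * out_len, -1) @ self.W.value + self.b.value
        y = _ACTIVATIONS[self.activation][0](z).reshape(b, out_len, self.channels_out)
        return y, (cols, y, length, need_input_grad)

    def backward(self, cache, dy: np.ndarray) -> np.ndarray | None:
        cols, y, length, need_input_grad = cache
        b, out_len, _ = dy.shape
        dz = dy * _ACTIVATIONS[self.activation][1](y)
        dz2 = dz.reshape(b * out_len, self.channels_out)
        cols2 = cols.reshape(b * out_len, -1)
        self.W.grad += cols2.T @ dz2
        self.b.grad += dz2.sum(axis=0)
        if not need_input_grad:
            return None
        dcols = (dz2 @ self.W.value.T).reshape(b, out_len, self.kernel_size,
                                               self.channels_in)
        p = self.padding
        dxp = np.zeros((b, length + 2 * p, self.channels_in), dtype=F32)
        for m in range(self.kernel_size):
            dxp[:, m:m + out_len, :] += dcols[:, :, m, :]
        return dxp[:, p:p + length, :] if p else dxp


def global_max_pool(x: np.ndarray):
    """Max over the position axis of (batch, length, channels) input."""
    idx = x.argmax(axis=1)
    y = np.take_along_axis(x, idx[:, None, :], axis=1)[:, 0, :]
    return y, (idx, x.shape)


def global_max_pool_backward(cache, dy: np.ndarray) -> np.ndarray:
    idx, shape = cache
    dx = np.zeros(shape, dtype=F32)
    np.put_along_axis(dx, idx[:, None, :], dy[:, None, :], axis=1)
    return dx


class Adam:
    """Adam optimizer over a list of Params."""

    def __init__(self, params: Iterable[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.value -= F32(lr) * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def cosine_annealing_lr(epoch: int, lr_max: float, cycle: int,
                        lr_min: float = 0.0) -> float:
    """Cosine-annealing learning rate with warm restarts every ``cycle`` epochs.

    At the start of each cycle (epoch % cycle == 0) the rate returns to
    ``lr_max``; within a cycle it decays along a half cosine to ``lr_min``.
    """
    if cycle < 1:
        raise ValueError("cycle must be >= 1")
    frac = (epoch % cycle) / cycle
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + math.cos(math.pi * frac))
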