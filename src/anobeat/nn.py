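"""Minimal feed-forward layer library with hand-written backprop.

Everything operates on numpy arrays with shapes ``(batch, time, channels)``
for sequence layers and ``(batch, features)`` after flattening.  Each layer
caches what its backward pass needs; ``backward`` consumes the gradient of
the loss w.r.t. its output, accumulates parameter gradients and returns the
gradient w.r.t. its input.  Gradients are verified against central finite
differences in the test suite.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = [
    "DEFAULT_DTYPE",
    "set_default_dtype",
    "default_dtype",
    "Param",
    "Layer",
    "Dense",
    "ReLU",
    "Tanh",
    "Sigmoid",
    "Dropout",
    "Flatten",
    "Reshape",
    "MaxPool1d",
    "Upsample1d",
    "Sequential",
    "Adam",
    "glorot_uniform",
]


# float32 is the working precision (2x SIMD throughput on one core);
# gradient-checking tests switch to float64 via default_dtype().
DEFAULT_DTYPE = np.dtype(np.float32)


def set_default_dtype(dtype) -> None:
    global DEFAULT_DTYPE
    DEFAULT_DTYPE = np.dtype(dtype)


@contextmanager
def default_dtype(dtype):
    """Temporarily change the dtype used by newly built layers."""
    global DEFAULT_DTYPE
    old = DEFAULT_DTYPE
    DEFAULT_DTYPE = np.dtype(dtype)
    try:
        yield
    finally:
        DEFAULT_DTYPE = old


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=DEFAULT_DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 name: str = "dense"):
        self.w = Param(f"{name}.w",
                       glorot_uniform(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(f"{name}.b", np.zeros(n_out))
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class Tanh(Layer):
    def forward(self, x, train=False, rng=None):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y**2)


class Sigmoid(Layer):
    def forward(self, x, train=False, rng=None):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity outside training mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | float = 1.0

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = 1.0
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = ((rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
                      ).astype(x.dtype)
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Reshape(Layer):
    """Reshape per-sample features to ``target`` (excluding batch axis)."""

    def __init__(self, target: tuple[int, ...]):
        self.target = target

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape((x.shape[0], *self.target))

    def backward(self, dy):
        return dy.reshape(self._shape)


class MaxPool1d(Layer):
    def __init__(self, factor: int):
        if factor < 1:
            raise ValueError("pool factor must be >= 1")
        self.factor = factor

    def forward(self, x, train=False, rng=None):
        b, t, c = x.shape
        if t % self.factor:
            raise ValueError(
                f"sequence length {t} not divisible by pool factor {self.factor}"
            )
        xr = x.reshape(b, t // self.factor, self.factor, c)
        self._argmax = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dy):
        b, to, c = dy.shape
        dxr = np.zeros((b, to, self.factor, c), dtype=dy.dtype)
        np.put_along_axis(dxr, self._argmax[:, :, None, :], dy[:, :, None, :],
                          axis=2)
        return dxr.reshape(self._in_shape)


class Upsample1d(Layer):
    """Nearest-neighbour repetition along the time axis."""

    def __init__(self, factor: int):
        if factor < 1:
            raise ValueError("upsample factor must be >= 1")
        self.factor = factor

    def forward(self, x, train=False, rng=None):
        return np.repeat(x, self.factor, axis=1)

    def backward(self, dy):
        b, t, c = dy.shape
        return dy.reshape(b, t // self.factor, self.factor, c).sum(axis=2)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def parameters(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x, train=False, rng=None, trace: list | None = None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
            if trace is not None:
                trace.append((type(layer).__name__, x.shape[1:]))
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad**2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
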