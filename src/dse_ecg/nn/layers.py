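"""Layers with explicit forward/backward passes.

Convolutions act along the time axis only (kernel shape (k, 1)): the lead
axis is preserved end-to-end so inter-lead structure survives until the
global pooling, and the channel axis carries learned features.
"""
from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Parameter:
    __slots__ = ("value", "grad", "velocity", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.velocity = np.zeros_like(self.value)
        self.name = name


def truncated_normal(
    rng: np.random.Generator, shape, std: float
) -> np.ndarray:
    """Fan-in scaled truncated normal (resample beyond 2 sigma)."""
    out = rng.standard_normal(shape)
    bad = np.abs(out) > 2
    while bad.any():
        out[bad] = rng.standard_normal(bad.sum())
        bad = np.abs(out) > 2
    return (out * std).astype(DTYPE)


class Layer:
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Parameter]:
        return []


class Conv2dTime(Layer):
    """Conv2D with kernel (k, 1): temporal convolution applied per lead.

    'same' padding on the time axis; `stride` downsamples time only. Weight
    shape (k, c_in, c_out).
    """

    def __init__(
        self, k: int, c_in: int, c_out: int, stride: int = 1,
        rng: np.random.Generator | None = None, name: str = "conv",
    ):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (k * c_in))
        self.k, self.c_in, self.c_out, self.stride = k, c_in, c_out, stride
        self.weight = Parameter(truncated_normal(rng, (k, c_in, c_out), std), f"{name}.w")
        self.bias = Parameter(np.zeros(c_out), f"{name}.b")
        self._x_pad: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, t, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        if t % self.stride:
            raise ValueError(f"time length {t} not divisible by stride {self.stride}")
        pl, pr = (self.k - 1) // 2, self.k // 2
        x_pad = np.zeros((n, t + self.k - 1, w, c), dtype=DTYPE)
        x_pad[:, pl : pl + t] = x
        self._x_pad = x_pad if training else None
        self._t_in = t
        to = t // self.stride
        view = np.lib.stride_tricks.sliding_window_view(x_pad, self.k, axis=1)
        view = view[:, :: self.stride]  # (n, to, w, c, k)
        out = np.tensordot(view, self.weight.value, axes=([3, 4], [1, 0]))
        return (out + self.bias.value).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._x_pad is None:
            raise RuntimeError("backward called without a training forward pass")
        x_pad, s, k = self._x_pad, self.stride, self.k
        n, to, w, _ = dy.shape
        t = self._t_in
        pl = (k - 1) // 2
        dW = np.empty_like(self.weight.value)
        dx_pad = np.zeros_like(x_pad)
        for i in range(k):
            xs = x_pad[:, i : i + s * to : s]
            dW[i] = np.tensordot(xs, dy, axes=([0, 1, 2], [0, 1, 2]))
            dx_pad[:, i : i + s * to : s] += dy @ self.weight.value[i].T
        self.weight.grad += dW
        self.bias.grad += dy.sum(axis=(0, 1, 2))
        return dx_pad[:, pl : pl + t]


class BatchNorm(Layer):
    """Per-channel batch normalization over (batch, time, lead)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5, name: str = "bn"):
        self.gamma = Parameter(np.ones(c), f"{name}.gamma")
        self.beta = Parameter(np.zeros(c), f"{name}.beta")
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(DTYPE)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean) / std
        if training:
            self._cache = (xhat.astype(DTYPE), std.astype(DTYPE), axes)
        return (self.gamma.value * xhat + self.beta.value).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, std, axes = self._cache
        m = np.prod([dy.shape[a] for a in axes])
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) / std
        return dx.astype(DTYPE)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        # np.maximum propagates NaN, so divergence stays observable
        return np.maximum(x, 0).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0).astype(DTYPE)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        z = np.clip(x, -60.0, 60.0)  # avoid exp overflow in float32
        self._y = (1.0 / (1.0 + np.exp(-z))).astype(DTYPE)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return (dy * self._y * (1 - self._y)).astype(DTYPE)


class Dropout(Layer):
    """Inverted dropout; identity when evaluating or when rate is 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate, self.rng = rate, rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return (x * self._mask).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(DTYPE)


class MaxPoolTime(Layer):
    """(pool, 1) max pooling along the time axis (shortcut downsampling)."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, t, w, c = x.shape
        if t % self.pool:
            raise ValueError(f"time length {t} not divisible by pool {self.pool}")
        xr = x.reshape(n, t // self.pool, self.pool, w, c)
        self._argmax = xr.argmax(axis=2)
        self._shape = x.shape
        return xr.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, to, w, c = dy.shape
        dx = np.zeros((n, to, self.pool, w, c), dtype=DTYPE)
        idx = np.indices((n, to, w, c))
        dx[idx[0], idx[1], self._argmax, idx[2], idx[3]] = dy
        return dx.reshape(self._shape)


class ChannelPad(Layer):
    """Zero-pad the channel axis (shortcut channel adjustment)."""

    def __init__(self, c_in: int, c_out: int):
        if c_out < c_in:
            raise ValueError("cannot pad to fewer channels")
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if self.c_in == self.c_out:
            return x
        pad = [(0, 0)] * (x.ndim - 1) + [(0, self.c_out - self.c_in)]
        return np.pad(x, pad)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy[..., : self.c_in]


class GlobalAvgPool(Layer):
    """Average over (time, lead): (n, t, w, c) → (n, c)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, t, w, c = self._shape
        return (np.broadcast_to(dy[:, None, None, :], self._shape) / (t * w)).astype(DTYPE)


class Dense(Layer):
    def __init__(
        self, n_in: int, n_out: int,
        rng: np.random.Generator | None = None, name: str = "dense",
    ):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / n_in)
        self.weight = Parameter(truncated_normal(rng, (n_in, n_out), std), f"{name}.w")
        self.bias = Parameter(np.zeros(n_out), f"{name}.b")

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return (x @ self.weight.value + self.bias.value).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ dy
        self.bias.grad += dy.sum(axis=0)
        return (dy @ self.weight.value.T).astype(DTYPE)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy over the batch and its logit gradient.

    `labels` are integer class indices. For a uniform predictor over K
    classes the loss is ln K.
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.log(p[np.arange(n), labels] + 1e-300).mean())
    dlogits = p
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(DTYPE)
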