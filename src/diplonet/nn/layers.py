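"""Minimal feed-forward layer library with explicit backprop.

All layers operate on channel-last float32 arrays: convolutional layers on
``(batch, length, channels)``, dense layers on ``(batch, features)``. Each
layer caches what its backward pass needs during ``forward`` and returns
input gradients from ``backward``; parameter gradients accumulate in
``layer.grads``. Written against numpy only so that training runs in
environments without a deep-learning framework.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv1D",
    "Dense",
    "BatchNorm",
    "MaxPool1D",
    "GlobalAvgPool1D",
    "ELU",
    "ReLU",
    "Flatten",
]


class Layer:
    """Base class: parameter-free, shape-preserving identity."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Conv1D(Layer):
    """1-D convolution with 'same' padding and optional dilation.

    Weight shape is (width, in_channels, out_channels); forward is computed
    as one matmul per kernel tap so the inner loops stay in BLAS.
    """

    def __init__(self, in_channels: int, out_channels: int, width: int,
                 dilation: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        if width < 1 or dilation < 1:
            raise ValueError("width and dilation must be >= 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.width = width
        self.dilation = dilation
        rng = rng or np.random.default_rng()
        fan_in = width * in_channels
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(width, in_channels, out_channels))
        self.params = {"W": w.astype(np.float32), "b": np.zeros(out_channels, np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache: tuple | None = None

    @property
    def _pad(self) -> tuple[int, int]:
        span = (self.width - 1) * self.dilation
        return span // 2, span - span // 2

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, length, cin = x.shape
        if cin != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {cin}")
        left, right = self._pad
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
        w, b = self.params["W"], self.params["b"]
        y = np.broadcast_to(b, (n, length, self.out_channels)).copy()
        for k in range(self.width):
            off = k * self.dilation
            y += xp[:, off:off + length, :] @ w[k]
        self._cache = (xp, x.shape)
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, x_shape = self._cache
        n, length, _ = x_shape
        left, _ = self._pad
        w = self.params["W"]
        self.grads["b"] += dout.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        flat_dout = dout.reshape(-1, self.out_channels)
        for k in range(self.width):
            off = k * self.dilation
            sl = xp[:, off:off + length, :]
            self.grads["W"][k] += sl.reshape(-1, self.in_channels).T @ flat_dout
            dxp[:, off:off + length, :] += dout @ w[k].T
        return dxp[:, left:left + length, :]


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        self.params = {"W": w.astype(np.float32), "b": np.zeros(out_features, np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


class BatchNorm(Layer):
    """Normalizes over every axis except the last (channel) axis.

    Running statistics (exponential moving average) are used when
    ``train=False``; batch statistics otherwise.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params = {
            "gamma": np.ones(channels, np.float32),
            "beta": np.zeros(channels, np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(np.float32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean) / std
        self._cache = (xhat, std, axes, train)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std, axes, train = self._cache
        self.grads["gamma"] += (dout * xhat).sum(axis=axes)
        self.grads["beta"] += dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"]
        if not train:
            return dxhat / std
        m = np.prod([xhat.shape[a] for a in axes])
        return (dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)) / std


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the length axis (trailing remainder
    positions are dropped, matching common framework defaults)."""

    def __init__(self, width: int = 2):
        super().__init__()
        self.width = width
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, length, c = x.shape
        lo = length // self.width
        xr = x[:, :lo * self.width, :].reshape(n, lo, self.width, c)
        idx = xr.argmax(axis=2)
        self._cache = (idx, x.shape)
        return np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, x_shape = self._cache
        n, length, c = x_shape
        lo = dout.shape[1]
        dxr = np.zeros((n, lo, self.width, c), dout.dtype)
        np.put_along_axis(dxr, idx[:, :, None, :], dout[:, :, None, :], axis=2)
        dx = np.zeros(x_shape, dout.dtype)
        dx[:, :lo * self.width, :] = dxr.reshape(n, lo * self.width, c)
        return dx


class GlobalAvgPool1D(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._length = 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._length = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.repeat(dout[:, None, :], self._length, axis=1) / self._length


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        neg = x < 0
        y = np.where(neg, self.alpha * np.expm1(np.minimum(x, 0.0)), x)
        self._cache = (neg, y)
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        neg, y = self._cache
        return dout * np.where(neg, y + self.alpha, 1.0)


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Flatten(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)
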