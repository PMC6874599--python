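"""Minimal feed-forward network engine: 1-D convolutions, dense layers,
ReLU, inverted dropout, mean-squared-error loss and the Adam optimizer.

The surrogate network is small (three convolutional layers, ~10^5 weights),
so a vectorised numpy implementation trains it in seconds.  Convolutions are
evaluated by an im2col strided view followed by a single matrix product;
gradients flow back through the same reshapes.  All randomness (weight
initialisation, shuffling, dropout masks) is drawn from one
``numpy.random.Generator`` so training is reproducible bit-for-bit on a given
platform.

A 3 x W image whose first convolution kernel spans all three rows is
mathematically a 1-D convolution with three input channels; that is how the
input encoding is consumed here.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                    shape: tuple, gain: float = 1.0) -> np.ndarray:
    limit = gain * np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    """Base class; layers with weights expose ``params`` / ``grads`` dicts."""

    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Valid (un-padded) 1-D convolution, stride >= 1.

    Input (N, C_in, W) -> output (N, C_out, W_out) with
    W_out = floor((W - kernel) / stride) + 1.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, rng: np.random.Generator,
                 gain: float = 1.0) -> None:
        super().__init__()
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel, self.stride = kernel, stride
        fan_in = in_channels * kernel
        self.params = {
            "W": _glorot_uniform(rng, fan_in, out_channels,
                                 (out_channels, in_channels, kernel), gain),
            "b": np.zeros(out_channels, dtype=DTYPE),
        }

    def _windows(self, x: np.ndarray) -> np.ndarray:
        n, c, w = x.shape
        w_out = (w - self.kernel) // self.stride + 1
        if w_out < 1:
            raise ValueError(
                f"kernel {self.kernel} exceeds feature-map width {w}")
        sn, sc, sw = x.strides
        return np.lib.stride_tricks.as_strided(
            x, shape=(n, w_out, c, self.kernel),
            strides=(sn, sw * self.stride, sc, sw), writeable=False)

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        n = x.shape[0]
        win = self._windows(x)                       # (N, Wo, C, K)
        w_out = win.shape[1]
        cols = win.reshape(n * w_out, -1)            # (N*Wo, C*K)
        wf = self.params["W"].reshape(self.out_channels, -1)
        y = cols @ wf.T + self.params["b"]           # (N*Wo, F)
        self._cache = (x, cols, n, w_out)
        return y.reshape(n, w_out, self.out_channels).transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, cols, n, w_out = self._cache
        dyf = dy.transpose(0, 2, 1).reshape(n * w_out, self.out_channels)
        self.grads["W"] = (dyf.T @ cols).reshape(self.params["W"].shape)
        self.grads["b"] = dyf.sum(axis=0)
        wf = self.params["W"].reshape(self.out_channels, -1)
        dcols = (dyf @ wf).reshape(n, w_out, self.in_channels, self.kernel)
        dx = np.zeros_like(x)
        for k in range(self.kernel):  # scatter each kernel tap back
            dx[:, :, k:k + self.stride * w_out:self.stride] += \
                dcols[:, :, :, k].transpose(0, 2, 1)
        return dx


class Dense(Layer):
    """Fully connected layer: (N, D_in) -> (N, D_out)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 gain: float = 1.0) -> None:
        super().__init__()
        self.params = {
            "W": _glorot_uniform(rng, d_in, d_out, (d_in, d_out), gain),
            "b": np.zeros(d_out, dtype=DTYPE),
        }

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout: active only during training."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Sequential:
    """An ordered stack of layers with joint forward/backward passes."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(l, k) for l in self.layers for k in l.params]

    def n_parameters(self) -> int:
        return sum(l.params[k].size for l, k in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [l.params[k].copy() for l, k in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (l, k), w in zip(self.parameters(), weights, strict=True):
            l.params[k] = w.astype(DTYPE).copy()


class Adam:
    """Adaptive moment estimation with bias correction."""

    def __init__(self, net: Sequential, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.net, self.lr = net, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(l.params[k]) for l, k in net.parameters()]
        self.v = [np.zeros_like(l.params[k]) for l, k in net.parameters()]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for i, (l, k) in enumerate(self.net.parameters()):
            g = l.grads[k]
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            l.params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)


def mse(pred: np.ndarray, truth: np.ndarray) -> float:
    return float(np.mean((pred - truth) ** 2))
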