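"""Trainable layers with explicit forward/backward passes.

Each layer stores its parameters and their gradients in ``params`` /
``grads`` dicts keyed by name. ``forward`` caches whatever the matching
``backward`` needs; layers are therefore stateful between a forward and
its backward, like any tape-free implementation. Evaluation-mode forward
passes (``training=False``) are deterministic for fixed weights.
"""

from __future__ import annotations

import numpy as np

from . import functional as F

__all__ = [
    "Layer",
    "Conv2d",
    "OperationalConv2d",
    "ConvTranspose2x2",
    "BatchNorm2d",
    "ReLU",
    "Tanh",
    "MaxPool2x2",
    "Dense",
    "Sequential",
]


def uniform_fan_in(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
                   dtype=np.float32, scale: float = 1.0) -> np.ndarray:
    """Fan-in-scaled uniform init, U(-sqrt(1/fan_in), sqrt(1/fan_in)) * scale."""
    bound = scale / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv2d(Layer):
    """Stride-1 2D convolution (cross-correlation) with bias."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 padding: str = "same", rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding mode {padding!r}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.pad = (kernel_size - 1) // 2 if padding == "same" else 0
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        self.params["weight"] = uniform_fan_in(
            rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in, dtype)
        self.params["bias"] = np.zeros(out_channels, dtype=dtype)
        self.zero_grad()

    def forward(self, x, training=False):
        self._x = x
        y = F.conv2d(x, self.params["weight"], pad=self.pad)
        return y + self.params["bias"][None, :, None, None]

    def backward(self, dy):
        w = self.params["weight"]
        self.grads["weight"] += F.conv2d_weight_grad(
            self._x, dy, w.shape[2], w.shape[3], self.pad)
        self.grads["bias"] += dy.sum(axis=(0, 2, 3))
        return F.conv2d_input_grad(dy, w, self.pad, self._x.shape[2:])


class OperationalConv2d(Layer):
    """Self-organized operational convolution layer.

    Each connection applies a learned Q-th-order polynomial (a truncated
    Taylor expansion around 0) of its input instead of a linear tap: the
    output is ``bias + sum_q conv(x**q, bank_q)`` for q = 1..Q, so bank q
    holds the q-th-order polynomial coefficients of every tap. The
    constant Taylor term is folded into the per-output-channel bias.
    Q = 1 reduces the layer to a conventional convolution.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 q_order: int = 3, padding: str = "same",
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        if q_order < 1:
            raise ValueError("q_order must be >= 1")
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding mode {padding!r}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.q_order = q_order
        self.pad = (kernel_size - 1) // 2 if padding == "same" else 0
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        # Higher-order banks start an order of magnitude smaller so the
        # layer begins near-linear and the polynomial terms grow in as
        # training finds them useful.
        banks = np.stack([
            uniform_fan_in(rng, (out_channels, in_channels, kernel_size, kernel_size),
                           fan_in, dtype, scale=1.0 if q == 0 else 0.1)
            for q in range(q_order)
        ])
        self.params["banks"] = banks
        self.params["bias"] = np.zeros(out_channels, dtype=dtype)
        self.zero_grad()

    def forward(self, x, training=False):
        self._powers = [x]
        for _ in range(1, self.q_order):
            self._powers.append(self._powers[-1] * x)
        banks = self.params["banks"]
        y = self.params["bias"][None, :, None, None].astype(x.dtype) * np.ones(
            (x.shape[0], 1, 1, 1), dtype=x.dtype)
        out = None
        for q in range(self.q_order):
            t = F.conv2d(self._powers[q], banks[q], pad=self.pad)
            out = t if out is None else out + t
        return out + y

    def backward(self, dy):
        banks = self.params["banks"]
        k = self.kernel_size
        x = self._powers[0]
        dx = None
        for q in range(self.q_order):
            self.grads["banks"][q] += F.conv2d_weight_grad(
                self._powers[q], dy, k, k, self.pad)
            g = F.conv2d_input_grad(dy, banks[q], self.pad, x.shape[2:])
            # d(x**(q+1))/dx = (q+1) * x**q
            if q > 0:
                g = g * ((q + 1) * self._powers[q - 1])
            dx = g if dx is None else dx + g
        self.grads["bias"] += dy.sum(axis=(0, 2, 3))
        return dx


class ConvTranspose2x2(Layer):
    """2x2-kernel, stride-2 transposed convolution (non-overlapping upsample)."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        rng = rng or np.random.default_rng()
        self.params["weight"] = uniform_fan_in(
            rng, (in_channels, out_channels, 2, 2), in_channels, dtype)
        self.params["bias"] = np.zeros(out_channels, dtype=dtype)
        self.zero_grad()

    def forward(self, x, training=False):
        self._x = x
        n, c, h, w = x.shape
        y = np.einsum("ncij,coab->noiajb", x, self.params["weight"], optimize=True)
        y = y.reshape(n, self.out_channels, 2 * h, 2 * w)
        return y + self.params["bias"][None, :, None, None]

    def backward(self, dy):
        n, o, h2, w2 = dy.shape
        h, w = h2 // 2, w2 // 2
        dy6 = dy.reshape(n, o, h, 2, w, 2)
        self.grads["weight"] += np.einsum(
            "ncij,noiajb->coab", self._x, dy6, optimize=True)
        self.grads["bias"] += dy.sum(axis=(0, 2, 3))
        return np.einsum("noiajb,coab->ncij", dy6, self.params["weight"], optimize=True)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics.

    Running statistics are frozen (and used) in evaluation mode, so
    inference is deterministic.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.zero_grad()

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = x.shape[0] * x.shape[2] * x.shape[3]
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(self.running_mean.dtype)
            # unbiased running variance, biased batch variance for normalization
            unbiased = var * m / max(m - 1, 1)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        self._training = training
        return (self.params["gamma"][None, :, None, None] * self._xhat
                + self.params["beta"][None, :, None, None])

    def backward(self, dy):
        xhat, std = self._xhat, self._std
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        if not self._training:
            return dy * g / std[None, :, None, None]
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return dx / std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Tanh(Layer):
    def forward(self, x, training=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y * self._y)


class MaxPool2x2(Layer):
    def forward(self, x, training=False):
        y, self._idx, _ = F.maxpool2x2(x)
        self._in_shape = x.shape
        return y

    def backward(self, dy):
        return F.maxpool2x2_grad(dy, self._idx, self._in_shape)


class Dense(Layer):
    """Fully connected layer on flattened (N, D) inputs."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        rng = rng or np.random.default_rng()
        self.params["weight"] = uniform_fan_in(
            rng, (out_features, in_features), in_features, dtype)
        self.params["bias"] = np.zeros(out_features, dtype=dtype)
        self.zero_grad()

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["weight"].T + self.params["bias"]

    def backward(self, dy):
        self.grads["weight"] += dy.T @ self._x
        self.grads["bias"] += dy.sum(axis=0)
        return dy @ self.params["weight"]


class Sequential(Layer):
    """Chain of layers; exposes the union of their parameters."""

    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def n_params(self):
        return sum(layer.n_params() for layer in self.layers)

    def named_params(self, prefix=""):
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Sequential):
                yield from layer.named_params(f"{prefix}{i}.")
            else:
                for k in layer.params:
                    yield f"{prefix}{i}.{k}", layer, k
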