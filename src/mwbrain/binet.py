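"""BINet: a six-operational-layer Self-ONN classifier.

Six blocks of operational convolution (3x3 kernels, same padding) ->
tanh -> 2x2 max-pool (odd sizes floor-divide), a flatten, and a single
three-neuron dense layer under softmax classify an image as non-tumor,
single tumor or double tumor. The first four operational layers have 8
output channels, the last two 16; the polynomial order Q defaults to 3,
and Q = 1 collapses every block to a plain convolution, giving the
vanilla 6-layer CNN baseline on the identical graph.

At the default 224x224 input the six floor-halvings leave a 3x3x16
activation, i.e. a 144-neuron flatten. No normalization layers are used;
tanh keeps activations bounded in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam, Dense, MaxPool2x2, OperationalConv2d, Sequential, Tanh
from .nn.functional import softmax
from .nn.layers import Layer

__all__ = [
    "BINetConfig",
    "ClassProbabilities",
    "BINet",
    "build_binet",
    "classify",
    "flatten_dim",
]


@dataclass(frozen=True)
class BINetConfig:
    in_channels: int = 3
    layer_channels: tuple[int, ...] = (8, 8, 8, 8, 16, 16)
    kernel_size: int = 3
    pool_size: int = 2
    q_order: int = 3
    input_size: int = 224
    num_classes: int = 3

    def __post_init__(self):
        if len(self.layer_channels) != 6:
            raise ValueError("BINet is defined with exactly six operational layers")
        if self.q_order < 1:
            raise ValueError("q_order must be >= 1")
        if self.pool_size != 2:
            raise ValueError("only 2x2 pooling is defined")
        if _final_spatial(self.input_size, len(self.layer_channels)) < 1:
            raise ValueError(
                f"input_size {self.input_size} too small for six 2x2 poolings")


@dataclass
class ClassProbabilities:
    """Softmax distribution over (non-tumor, single tumor, double tumor)."""

    probabilities: np.ndarray  # (3,), non-negative, sums to 1

    @property
    def predicted(self) -> int:
        return int(np.argmax(self.probabilities))


def _final_spatial(size: int, n_blocks: int) -> int:
    for _ in range(n_blocks):
        size //= 2
    return size


def flatten_dim(config: BINetConfig | None = None) -> int:
    """Flattened feature length after the six pool stages (floor division)."""
    config = config or BINetConfig()
    s = _final_spatial(config.input_size, len(config.layer_channels))
    return s * s * config.layer_channels[-1]


class BINet(Layer):
    def __init__(self, config: BINetConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.config = config or BINetConfig()
        rng = rng or np.random.default_rng()
        blocks = []
        cin = self.config.in_channels
        for cout in self.config.layer_channels:
            blocks += [
                OperationalConv2d(cin, cout, kernel_size=self.config.kernel_size,
                                  q_order=self.config.q_order, padding="same",
                                  rng=rng),
                Tanh(),
                MaxPool2x2(),
            ]
            cin = cout
        self.features = Sequential(*blocks)
        self.dense = Dense(flatten_dim(self.config), self.config.num_classes, rng=rng)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected NCHW input with {self.config.in_channels} channels, "
                f"got shape {x.shape}")
        if x.shape[2] != self.config.input_size or x.shape[3] != self.config.input_size:
            raise ValueError(
                f"expected {self.config.input_size}x{self.config.input_size} input, "
                f"got {x.shape[2]}x{x.shape[3]}")
        h = self.features.forward(x, training)
        self._feat_shape = h.shape
        return self.dense.forward(h.reshape(h.shape[0], -1), training)

    def flat_features(self, x: np.ndarray) -> np.ndarray:
        """Flattened activation after the six blocks (for contract checks)."""
        h = self.features.forward(x, training=False)
        return h.reshape(h.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.dense.backward(dy).reshape(self._feat_shape)
        return self.features.backward(dh)

    def zero_grad(self):
        self.features.zero_grad()
        self.dense.zero_grad()

    def n_params(self):
        return self.features.n_params() + self.dense.n_params()

    def param_handles(self):
        handles = [(layer, k) for _, layer, k in self.features.named_params()]
        handles += [(self.dense, k) for k in self.dense.params]
        return handles

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.param_handles(), lr=lr)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for name, layer, k in self.features.named_params():
            state[f"features.{name}"] = layer.params[k]
        for k in self.dense.params:
            state[f"dense.{k}"] = self.dense.params[k]
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer, k in self.features.named_params():
            layer.params[k][...] = state[f"features.{name}"]
        for k in self.dense.params:
            self.dense.params[k][...] = state[f"dense.{k}"]

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path, config: BINetConfig | None = None) -> "BINet":
        net = cls(config)
        with np.load(path) as data:
            net.load_state_dict(dict(data))
        return net


def build_binet(config: BINetConfig | None = None,
                rng: np.random.Generator | None = None) -> BINet:
    return BINet(config, rng)


def classify(network: BINet, image: np.ndarray) -> ClassProbabilities:
    """Evaluation-mode class probabilities for one (H, W, C) image."""
    cfg = network.config
    if image.ndim != 3 or image.shape != (cfg.input_size, cfg.input_size, cfg.in_channels):
        raise ValueError(
            f"expected ({cfg.input_size}, {cfg.input_size}, {cfg.in_channels}) image, "
            f"got {image.shape}")
    x = image.transpose(2, 0, 1)[None].astype(np.float32)
    logits = network.forward(x, training=False)
    return ClassProbabilities(probabilities=softmax(logits, axis=1)[0])
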