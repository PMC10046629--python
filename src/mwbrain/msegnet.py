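"""MSegNet: a lightweight 2-level encoder-decoder tumor segmenter.

A U-shaped network cut down to two encoding and two decoding blocks so
it stays small enough for portable deployment. Each encoder block is two
3x3 conv + batch-norm + ReLU stages followed by a 2x2 max-pool; a
bottleneck (two conv stages at 4x the initial feature width) joins the
paths; each decoder block upsamples with a 2x2 stride-2 transposed
convolution, applies a 3x3 conv stage, concatenates the matching encoder
skip and applies another 3x3 conv stage. A final 1x1 convolution maps to
two channels (background / tumor) under a per-pixel softmax. Channel
widths run 32 -> 64 -> 128 -> 64 -> 32 at the default feature width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2x2,
    MaxPool2x2,
    Sequential,
)
from .nn.functional import softmax
from .nn.layers import Layer, ReLU

__all__ = [
    "MSegNetConfig",
    "SegmentationOutput",
    "MSegNet",
    "build_msegnet",
    "segment",
    "msegnet_param_count",
]


@dataclass(frozen=True)
class MSegNetConfig:
    in_channels: int = 3
    initial_features: int = 32
    levels: int = 2
    out_classes: int = 2
    input_size: int = 256

    def __post_init__(self):
        if self.levels != 2:
            raise ValueError("MSegNet is defined with exactly two levels")
        if self.out_classes != 2:
            raise ValueError("MSegNet is a binary (background/tumor) segmenter")
        if self.input_size % (2 ** self.levels) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by {2 ** self.levels}")


@dataclass
class SegmentationOutput:
    probabilities: np.ndarray  # (H, W, 2), per-pixel class distribution
    mask: np.ndarray           # (H, W) uint8 in {0, 1}


def _conv_bn_relu(cin: int, cout: int, rng, kernel_size: int = 3) -> Sequential:
    return Sequential(
        Conv2d(cin, cout, kernel_size=kernel_size, padding="same", rng=rng),
        BatchNorm2d(cout),
        ReLU(),
    )


class MSegNet(Layer):
    def __init__(self, config: MSegNetConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.config = config or MSegNetConfig()
        rng = rng or np.random.default_rng()
        f = self.config.initial_features
        cin = self.config.in_channels

        self.enc1 = Sequential(*_conv_bn_relu(cin, f, rng).layers,
                               *_conv_bn_relu(f, f, rng).layers)
        self.pool1 = MaxPool2x2()
        self.enc2 = Sequential(*_conv_bn_relu(f, 2 * f, rng).layers,
                               *_conv_bn_relu(2 * f, 2 * f, rng).layers)
        self.pool2 = MaxPool2x2()
        self.bottleneck = Sequential(*_conv_bn_relu(2 * f, 4 * f, rng).layers,
                                     *_conv_bn_relu(4 * f, 4 * f, rng).layers)
        self.up1 = ConvTranspose2x2(4 * f, 2 * f, rng=rng)
        self.dec1a = _conv_bn_relu(2 * f, 2 * f, rng)
        self.dec1b = _conv_bn_relu(4 * f, 2 * f, rng)
        self.up2 = ConvTranspose2x2(2 * f, f, rng=rng)
        self.dec2a = _conv_bn_relu(f, f, rng)
        self.dec2b = _conv_bn_relu(2 * f, f, rng)
        self.head = Conv2d(f, self.config.out_classes, kernel_size=1,
                           padding="valid", rng=rng)
        self._modules: list[tuple[str, Layer]] = [
            ("enc1", self.enc1), ("enc2", self.enc2),
            ("bottleneck", self.bottleneck),
            ("up1", self.up1), ("dec1a", self.dec1a), ("dec1b", self.dec1b),
            ("up2", self.up2), ("dec2a", self.dec2a), ("dec2b", self.dec2b),
            ("head", self.head),
        ]

    # -- forward / backward with skip wiring --

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected NCHW input with {self.config.in_channels} channels, "
                f"got shape {x.shape}")
        if x.shape[2] % 4 or x.shape[3] % 4:
            raise ValueError("spatial size must be divisible by 4")
        f = self.config.initial_features
        e1 = self.enc1.forward(x, training)
        e2 = self.enc2.forward(self.pool1.forward(e1, training), training)
        b = self.bottleneck.forward(self.pool2.forward(e2, training), training)
        d1a = self.dec1a.forward(self.up1.forward(b, training), training)
        d1 = self.dec1b.forward(np.concatenate([d1a, e2], axis=1), training)
        d2a = self.dec2a.forward(self.up2.forward(d1, training), training)
        d2 = self.dec2b.forward(np.concatenate([d2a, e1], axis=1), training)
        self._f = f
        return self.head.forward(d2, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        f = self._f
        d_c2 = self.dec2b.backward(self.head.backward(dy))
        d_d2a, d_e1_skip = d_c2[:, :f], d_c2[:, f:]
        d_d1 = self.up2.backward(self.dec2a.backward(d_d2a))
        d_c1 = self.dec1b.backward(d_d1)
        d_d1a, d_e2_skip = d_c1[:, : 2 * f], d_c1[:, 2 * f:]
        d_b = self.up1.backward(self.dec1a.backward(d_d1a))
        d_p2 = self.bottleneck.backward(d_b)
        d_e2 = self.pool2.backward(d_p2) + d_e2_skip
        d_p1 = self.enc2.backward(d_e2)
        d_e1 = self.pool1.backward(d_p1) + d_e1_skip
        return self.enc1.backward(d_e1)

    # -- bookkeeping --

    def zero_grad(self):
        for _, m in self._modules:
            m.zero_grad()

    def n_params(self):
        return sum(m.n_params() for _, m in self._modules)

    def param_handles(self):
        handles = []
        for name, m in self._modules:
            if isinstance(m, Sequential):
                handles.extend((layer, k) for _, layer, k in m.named_params())
            else:
                handles.extend((m, k) for k in m.params)
        return handles

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.param_handles(), lr=lr)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for name, m in self._modules:
            layers = m.layers if isinstance(m, Sequential) else [m]
            for i, layer in enumerate(layers):
                for k, v in layer.params.items():
                    state[f"{name}.{i}.{k}"] = v
                if isinstance(layer, BatchNorm2d):
                    state[f"{name}.{i}.running_mean"] = layer.running_mean
                    state[f"{name}.{i}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, m in self._modules:
            layers = m.layers if isinstance(m, Sequential) else [m]
            for i, layer in enumerate(layers):
                for k in layer.params:
                    layer.params[k][...] = state[f"{name}.{i}.{k}"]
                if isinstance(layer, BatchNorm2d):
                    layer.running_mean[...] = state[f"{name}.{i}.running_mean"]
                    layer.running_var[...] = state[f"{name}.{i}.running_var"]

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path, config: MSegNetConfig | None = None) -> "MSegNet":
        net = cls(config)
        with np.load(path) as data:
            net.load_state_dict(dict(data))
        return net


def build_msegnet(config: MSegNetConfig | None = None,
                  rng: np.random.Generator | None = None) -> MSegNet:
    return MSegNet(config, rng)


def segment(network: MSegNet, image: np.ndarray) -> SegmentationOutput:
    """Evaluation-mode segmentation of one (H, W, C) image.

    Probability ties at exactly 0.5 resolve to background (conservative
    tumor calls), so the mask is ``p_tumor > 0.5``.
    """
    if image.ndim != 3 or image.shape[2] != network.config.in_channels:
        raise ValueError(f"expected (H, W, {network.config.in_channels}) image")
    x = image.transpose(2, 0, 1)[None].astype(np.float32)
    logits = network.forward(x, training=False)
    probs = softmax(logits, axis=1)[0]  # (2, H, W)
    mask = (probs[1] > 0.5).astype(np.uint8)
    return SegmentationOutput(probabilities=probs.transpose(1, 2, 0), mask=mask)


def msegnet_param_count(config: MSegNetConfig | None = None) -> int:
    """Analytic trainable-parameter count for the layer list above."""
    config = config or MSegNetConfig()
    f, cin, out = config.initial_features, config.in_channels, config.out_classes

    def conv(ci, co, k=3):
        return co * ci * k * k + co

    def bn(c):
        return 2 * c

    def convt(ci, co):
        return ci * co * 4 + co

    total = 0
    for ci, co in [(cin, f), (f, f)]:
        total += conv(ci, co) + bn(co)
    for ci, co in [(f, 2 * f), (2 * f, 2 * f)]:
        total += conv(ci, co) + bn(co)
    for ci, co in [(2 * f, 4 * f), (4 * f, 4 * f)]:
        total += conv(ci, co) + bn(co)
    total += convt(4 * f, 2 * f)
    for ci, co in [(2 * f, 2 * f), (4 * f, 2 * f)]:
        total += conv(ci, co) + bn(co)
    total += convt(2 * f, f)
    for ci, co in [(f, f), (2 * f, f)]:
        total += conv(ci, co) + bn(co)
    total += conv(f, out, k=1)
    return total
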