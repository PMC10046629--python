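"""The Self-ONN operational convolution, from first principles.

A self-organized operational neural network (Self-ONN) replaces the
linear tap of a convolution with a learned polynomial of the input: a
truncated Taylor expansion around an anchor point ``a``. With a tanh
activation bounding activations to [-1, 1], the expansion anchor is 0,
so each connection computes

    psi(w, y) = sum_{q=1..Q} w_q * y**q

with the constant (order-0) Taylor term folded into a per-output-channel
bias. A whole operational layer is then

    out = bias + sum_{q=1..Q} conv2d(x**q, bank_q)

where bank q collects the order-q coefficients of every tap, so the
layer decomposes into Q plain convolutions of the element-wise input
powers. Q = 1 is exactly a conventional convolution.

This module is the small, inspectable reference surface; the trainable
layer used by the networks (:class:`mwbrain.nn.OperationalConv2d`)
shares the same convolution primitives and is tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import functional as F

__all__ = [
    "OperationalLayerSpec",
    "NodalWeights",
    "nodal_transform",
    "operational_conv_forward",
    "tanh_activation",
]

# TensorMap convention: a single image/feature map is an (H, W, C) float
# array; all values finite, H, W, C >= 1.


@dataclass(frozen=True)
class OperationalLayerSpec:
    """Shape/order contract for one operational layer."""

    in_channels: int
    out_channels: int
    kernel_size: int = 3
    q_order: int = 3
    padding: str = "same"
    anchor_a: float = field(default=0.0, init=False)  # tanh activation => a = 0

    def __post_init__(self):
        if self.q_order < 1:
            raise ValueError("q_order must be >= 1")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if self.padding not in ("same", "valid"):
            raise ValueError(f"unknown padding mode {self.padding!r}")


@dataclass
class NodalWeights:
    """Q kernel banks plus bias realizing the polynomial nodal operator.

    ``banks`` has shape (Q, out_channels, in_channels, k, k); bank q-1
    holds the order-q coefficients w_q of every tap.
    """

    banks: np.ndarray
    bias: np.ndarray

    def validate(self, spec: OperationalLayerSpec) -> None:
        expect = (spec.q_order, spec.out_channels, spec.in_channels,
                  spec.kernel_size, spec.kernel_size)
        if self.banks.shape != expect:
            raise ValueError(f"banks shape {self.banks.shape} != {expect}")
        if self.bias.shape != (spec.out_channels,):
            raise ValueError(f"bias shape {self.bias.shape} != ({spec.out_channels},)")


def nodal_transform(w: np.ndarray, y: float) -> float:
    """Evaluate the polynomial nodal operator psi(w, y) = sum_q w_q y^q.

    ``w`` lists the coefficients (w_1, ..., w_Q); the order-0 term lives
    in the layer bias and is not part of this transform.
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValueError("coefficient vector must be 1-D with Q >= 1 entries")
    powers = np.power(float(y), np.arange(1, w.size + 1))
    return float(w @ powers)


def operational_conv_forward(x: np.ndarray, weights: NodalWeights,
                             spec: OperationalLayerSpec) -> np.ndarray:
    """Forward pass of one operational layer on a single (H, W, C) map."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected an (H, W, C) tensor map")
    if x.shape[2] != spec.in_channels:
        raise ValueError(
            f"channel mismatch: input has {x.shape[2]}, spec expects {spec.in_channels}")
    weights.validate(spec)
    pad = (spec.kernel_size - 1) // 2 if spec.padding == "same" else 0
    xc = x.transpose(2, 0, 1)[None]  # -> NCHW
    out = None
    for q in range(spec.q_order):
        t = F.conv2d(xc ** (q + 1), np.asarray(weights.banks[q], dtype=float), pad=pad)
        out = t if out is None else out + t
    out = out + np.asarray(weights.bias, dtype=float)[None, :, None, None]
    return out[0].transpose(1, 2, 0)


def tanh_activation(x: np.ndarray) -> np.ndarray:
    """Element-wise tanh; outputs constrained to [-1, 1]."""
    return np.tanh(np.asarray(x, dtype=float))
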