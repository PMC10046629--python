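"""Low-level array ops for the layer engine.

All image batches are NCHW float arrays. Convolutions are stride-1
cross-correlations (deep-learning convention, no kernel flip); spatial
down/up-sampling is done by pooling and 2x2 stride-2 transposed
convolution, so stride-1 is the only convolution case needed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "pad2d",
    "conv2d",
    "conv2d_input_grad",
    "conv2d_weight_grad",
    "maxpool2x2",
    "maxpool2x2_grad",
    "softmax",
]


def pad2d(x: np.ndarray, pad: int) -> np.ndarray:
    """Zero-pad the two trailing (spatial) axes symmetrically."""
    if pad == 0:
        return x
    width = [(0, 0)] * (x.ndim - 2) + [(pad, pad), (pad, pad)]
    return np.pad(x, width)


def _windows(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    # (N, C, Ho, Wo, kh, kw) view over the padded input
    return sliding_window_view(x, (kh, kw), axis=(2, 3))


def conv2d(x: np.ndarray, w: np.ndarray, pad: int = 0) -> np.ndarray:
    """Stride-1 cross-correlation of NCHW ``x`` with OCkk kernels ``w``."""
    if x.ndim != 4 or w.ndim != 4:
        raise ValueError("conv2d expects NCHW input and OCkk kernels")
    if x.shape[1] != w.shape[1]:
        raise ValueError(
            f"channel mismatch: input has {x.shape[1]}, kernels expect {w.shape[1]}"
        )
    cols = _windows(pad2d(x, pad), w.shape[2], w.shape[3])
    return np.einsum("nchwij,ocij->nohw", cols, w, optimize=True)


def conv2d_input_grad(dy: np.ndarray, w: np.ndarray, pad: int, in_hw: tuple[int, int]) -> np.ndarray:
    """Gradient of conv2d w.r.t. its input (full correlation with flipped kernels)."""
    kh, kw = w.shape[2], w.shape[3]
    w_t = np.ascontiguousarray(w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
    dx = conv2d(dy, w_t, pad=kh - 1 - pad)
    # stride-1 'valid'/'same' both land on exactly the input size; guard anyway
    if dx.shape[2:] != in_hw:
        raise AssertionError("input-gradient shape mismatch")
    return dx


def conv2d_weight_grad(x: np.ndarray, dy: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """Gradient of conv2d w.r.t. the kernels."""
    cols = _windows(pad2d(x, pad), kh, kw)
    return np.einsum("nchwij,nohw->ocij", cols, dy, optimize=True)


def maxpool2x2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """2x2/stride-2 max pool with floor division of odd sizes.

    Returns (pooled, argmax indices in each 2x2 window, cropped input H/W).
    """
    n, c, h, w = x.shape
    hp, wp = h // 2, w // 2
    if hp == 0 or wp == 0:
        raise ValueError(f"spatial size {h}x{w} too small for 2x2 pooling")
    r = x[:, :, : 2 * hp, : 2 * wp]
    r = r.reshape(n, c, hp, 2, wp, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, hp, wp, 4)
    idx = r.argmax(axis=-1)
    y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return y, idx, (2 * hp, 2 * wp)


def maxpool2x2_grad(dy: np.ndarray, idx: np.ndarray, in_shape: tuple[int, ...]) -> np.ndarray:
    """Scatter pooled gradients back to the (first-max) argmax positions."""
    n, c, h, w = in_shape
    hp, wp = dy.shape[2], dy.shape[3]
    flat = np.zeros((n, c, hp, wp, 4), dtype=dy.dtype)
    np.put_along_axis(flat, idx[..., None], dy[..., None], axis=-1)
    dx = np.zeros(in_shape, dtype=dy.dtype)
    dx[:, :, : 2 * hp, : 2 * wp] = (
        flat.reshape(n, c, hp, wp, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, 2 * hp, 2 * wp)
    )
    return dx


def softmax(x: np.ndarray, axis: int = 1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
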