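"""Geometric augmentation of image/mask pairs.

Three transform families expand each fold's training originals into a
fixed-size training set: rotation (3-50 degrees, either direction),
scaling (2-15% shrink or enlarge) and translation (3-10% of the frame,
horizontal and vertical, either sign). One draw samples all three
families jointly into a single affine transform; images are warped with
bilinear interpolation, masks with nearest-neighbor so they stay binary,
and out-of-frame pixels are zero-filled. Draws that change the mask's
connected-component count (a tumor pushed out of frame or merged) are
rejected and redrawn so labels stay correct.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
from scipy import ndimage
from skimage.transform import AffineTransform, warp

from .synthetic_data import LABELS, LabeledSample

__all__ = [
    "PolicyError",
    "AugmentationError",
    "TransformParams",
    "AugmentationPolicy",
    "augment_sample",
    "iter_expanded",
    "expand_training_set",
]


class PolicyError(ValueError):
    """Drawn transform parameters fall outside the policy's ranges."""


class AugmentationError(RuntimeError):
    """No label-preserving transform could be drawn within the retry budget."""


@dataclass(frozen=True)
class TransformParams:
    """One drawn geometric transform.

    ``rotation_deg`` is signed (counterclockwise positive); ``scale`` is
    the magnification factor (1.0 = none); ``translate_frac`` is the
    signed (vertical, horizontal) shift as a fraction of the frame.
    """

    rotation_deg: float = 0.0
    scale: float = 1.0
    translate_frac: tuple[float, float] = (0.0, 0.0)

    @property
    def is_identity(self) -> bool:
        return (self.rotation_deg == 0.0 and self.scale == 1.0
                and self.translate_frac == (0.0, 0.0))


@dataclass(frozen=True)
class AugmentationPolicy:
    rotation_degrees: tuple[float, float] = (3.0, 50.0)
    scale_percent: tuple[float, float] = (2.0, 15.0)
    translate_percent: tuple[float, float] = (3.0, 10.0)
    target_total: int = 6000
    seed: int = 0

    def draw(self, rng: np.random.Generator) -> TransformParams:
        rot = rng.uniform(*self.rotation_degrees) * rng.choice([-1.0, 1.0])
        mag = rng.uniform(*self.scale_percent) / 100.0
        scale = 1.0 + mag * rng.choice([-1.0, 1.0])
        ty = rng.uniform(*self.translate_percent) / 100.0 * rng.choice([-1.0, 1.0])
        tx = rng.uniform(*self.translate_percent) / 100.0 * rng.choice([-1.0, 1.0])
        return TransformParams(rotation_deg=float(rot), scale=float(scale),
                               translate_frac=(float(ty), float(tx)))

    def validate(self, params: TransformParams) -> None:
        def _in(value, lo, hi, name):
            if not (lo <= value <= hi):
                raise PolicyError(f"{name} magnitude {value:.4g} outside [{lo}, {hi}]")

        if params.rotation_deg != 0.0:
            _in(abs(params.rotation_deg), *self.rotation_degrees, "rotation")
        if params.scale != 1.0:
            _in(abs(params.scale - 1.0) * 100.0, *self.scale_percent, "scale")
        for t in params.translate_frac:
            if t != 0.0:
                _in(abs(t) * 100.0, *self.translate_percent, "translation")


def _affine(params: TransformParams, shape: tuple[int, int]) -> AffineTransform:
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    center = AffineTransform(translation=(-cx, -cy))
    core = AffineTransform(rotation=np.deg2rad(params.rotation_deg),
                           scale=params.scale)
    ty, tx = params.translate_frac
    back = AffineTransform(translation=(cx + tx * w, cy + ty * h))
    return center + core + back


def augment_sample(sample: LabeledSample, params: TransformParams,
                   policy: AugmentationPolicy | None = None) -> LabeledSample:
    """Apply one transform identically to image (bilinear) and mask (nearest)."""
    if policy is not None:
        policy.validate(params)
    if params.is_identity:
        return replace(sample, sample_id=sample.sample_id + "_aug")
    tform = _affine(params, sample.mask.shape)
    image = warp(sample.image.astype(np.float64), tform.inverse, order=1,
                 mode="constant", cval=0.0, preserve_range=True).astype(np.float32)
    mask = warp(sample.mask, tform.inverse, order=0, mode="constant", cval=0,
                preserve_range=True).astype(np.uint8)
    return LabeledSample(image=image, mask=mask, label=sample.label,
                         sample_id=sample.sample_id + "_aug", tumors=[])


def _components(mask: np.ndarray) -> int:
    return int(ndimage.label(mask)[1])


def _interleave_by_class(originals: list[LabeledSample]) -> list[LabeledSample]:
    by_class = {label: [s for s in originals if s.label == label] for label in LABELS}
    order: list[LabeledSample] = []
    pools = [lst for lst in by_class.values() if lst]
    longest = max(len(lst) for lst in pools)
    for i in range(longest):
        for lst in pools:
            order.append(lst[i % len(lst)])
    return order


def iter_expanded(originals: list[LabeledSample], policy: AugmentationPolicy,
                  max_retries: int = 25) -> Iterator[LabeledSample]:
    """Stream exactly ``policy.target_total`` augmented samples.

    Originals are cycled in class-interleaved order so per-class output
    proportions match the input within one sample; each pass draws a
    fresh transform from the policy's seeded stream.
    """
    if not originals:
        raise ValueError("need at least one original sample")
    if policy.target_total < len(originals):
        raise ValueError("target_total must be >= number of originals")
    rng = np.random.default_rng(policy.seed)
    order = _interleave_by_class(list(originals))
    produced = 0
    i = 0
    while produced < policy.target_total:
        src = order[i % len(order)]
        i += 1
        n_src = _components(src.mask)
        for attempt in range(max_retries):
            params = policy.draw(rng)
            out = augment_sample(src, params)
            if _components(out.mask) == n_src:
                break
        else:
            raise AugmentationError(
                f"no component-preserving transform for {src.sample_id} "
                f"after {max_retries} draws")
        out = replace(out, sample_id=f"{src.sample_id}_aug{produced:05d}")
        produced += 1
        yield out


def expand_training_set(originals: list[LabeledSample],
                        policy: AugmentationPolicy) -> list[LabeledSample]:
    """Materialized version of :func:`iter_expanded`."""
    return list(iter_expanded(originals, policy))
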