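"""Seeded synthetic stand-in for reconstructed microwave (RMW) brain images.

The real study data — colormapped intensity fields reconstructed from a
nine-antenna scan of a four-layer tissue-mimicking head phantom — is
private, so this module emulates its geometry: a layered head ellipse
(dura/CSF/gray/white intensity rings), smooth multiplicative clutter plus
additive noise standing in for reconstruction artifacts, and each tumor a
bright Gaussian-profiled disk whose ground-truth mask is the disk at the
profile's half-maximum. Intensity is rendered to 3 channels through a
fixed, invertible jet-like pseudo-color transfer, mimicking the heatmap
renderings the classifier consumes.

Geometry defaults follow the imaging system's stated limits at the
256-px image size: minimum tumor radius 10 px (a 5 mm tumor at
0.2645833333 mm/px) and a minimum two-tumor separation of 38 px (10 mm);
both scale proportionally for smaller image sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "LABELS",
    "GenerationError",
    "PhantomSpec",
    "LabeledSample",
    "generate_sample",
    "generate_dataset",
    "intensity_to_rgb",
    "rgb_to_intensity",
    "save_dataset",
    "load_dataset",
]

LABELS = ("non_tumor", "single_tumor", "double_tumor")

_REF_SIZE = 256
_REF_MIN_RADIUS = 10  # 5 mm tumor at 0.2645833333 mm/px -> 19 px diameter
_REF_SEPARATION = 38  # 10 mm minimum two-tumor distance


class GenerationError(RuntimeError):
    """Raised when tumors cannot be placed under the spec's constraints."""


def _scaled(value: int, image_size: int, floor: int) -> int:
    return max(floor, round(value * image_size / _REF_SIZE))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise parameters of one synthetic phantom image."""

    image_size: int = 256
    head_axes: tuple[float, float] | None = None  # ellipse semi-axes (y, x), px
    n_layers: int = 4
    tumor_count: int = 1
    tumor_radius_range: tuple[int, int] | None = None
    min_separation: int | None = None
    noise_sigma: float = 0.04
    clutter_strength: float = 0.18

    def __post_init__(self):
        if self.tumor_count not in (0, 1, 2):
            raise ValueError("tumor_count must be 0, 1 or 2")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.head_axes is None:
            object.__setattr__(self, "head_axes",
                               (0.36 * self.image_size, 0.42 * self.image_size))
        if self.tumor_radius_range is None:
            lo = _scaled(_REF_MIN_RADIUS, self.image_size, 2)
            hi = _scaled(16, self.image_size, lo + 1)
            object.__setattr__(self, "tumor_radius_range", (lo, hi))
        if self.min_separation is None:
            object.__setattr__(self, "min_separation",
                               _scaled(_REF_SEPARATION, self.image_size, 4))
        lo, hi = self.tumor_radius_range
        min_r = _scaled(_REF_MIN_RADIUS, self.image_size, 2)
        if lo < min_r:
            raise ValueError(
                f"minimum tumor radius {lo} px below the {min_r} px detectability "
                f"floor at image_size {self.image_size}")
        if self.min_separation < _scaled(_REF_SEPARATION, self.image_size, 4):
            raise ValueError("min_separation below the system's two-tumor resolution")


@dataclass
class LabeledSample:
    """One image + ground-truth mask + class label."""

    image: np.ndarray  # (H, W, 3) float32 in [0, 1]
    mask: np.ndarray   # (H, W) uint8 in {0, 1}
    label: str         # one of LABELS
    sample_id: str
    tumors: list[tuple[float, float, float]] = field(default_factory=list)  # (cy, cx, r)

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


# --- pseudo-color transfer -------------------------------------------------

def intensity_to_rgb(t: np.ndarray) -> np.ndarray:
    """Fixed jet-like piecewise-linear transfer, intensity [0,1] -> RGB [0,1].

    The path through RGB space is injective, so the transfer is
    invertible up to quantization (see :func:`rgb_to_intensity`).
    """
    t = np.clip(np.asarray(t, dtype=np.float32), 0.0, 1.0)
    r = np.clip(1.5 - np.abs(4.0 * t - 3.0), 0.0, 1.0)
    g = np.clip(1.5 - np.abs(4.0 * t - 2.0), 0.0, 1.0)
    b = np.clip(1.5 - np.abs(4.0 * t - 1.0), 0.0, 1.0)
    return np.stack([r, g, b], axis=-1)


_LUT_T = np.linspace(0.0, 1.0, 1024).astype(np.float32)
_LUT_RGB = intensity_to_rgb(_LUT_T)


def rgb_to_intensity(rgb: np.ndarray) -> np.ndarray:
    """Invert the pseudo-color transfer by nearest point on the color curve."""
    rgb = np.asarray(rgb, dtype=np.float32)
    flat = rgb.reshape(-1, 3)
    d2 = ((flat[:, None, :] - _LUT_RGB[None, :, :]) ** 2).sum(axis=2)
    return _LUT_T[d2.argmin(axis=1)].reshape(rgb.shape[:-1])


# --- generation ------------------------------------------------------------

def _head_field(spec: PhantomSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Layered head intensity field and the normalized elliptical radius."""
    s = spec.image_size
    ay, ax = spec.head_axes
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float32)
    cy = cx = (s - 1) / 2.0
    re = np.sqrt(((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2)

    # concentric tissue rings, outermost thin (dura), inner bulk (white matter)
    edges = np.linspace(1.0, 0.0, spec.n_layers + 1)[1:-1]  # inner boundaries
    base_levels = np.linspace(0.55, 0.25, spec.n_layers)
    field = np.zeros((s, s), dtype=np.float32)
    layer = np.full((s, s), -1, dtype=int)
    inside = re <= 1.0
    layer[inside] = 0
    for i, edge in enumerate(edges):
        layer[re <= edge] = i + 1
    for i in range(spec.n_layers):
        field[layer == i] = base_levels[i]
    field = ndimage.gaussian_filter(field, sigma=s / 128.0)
    field[~inside] = 0.0

    # low-spatial-frequency multiplicative clutter + additive noise
    clutter = ndimage.gaussian_filter(
        rng.standard_normal((s, s)).astype(np.float32), sigma=s / 16.0)
    cstd = clutter.std()
    if cstd > 0:
        clutter /= cstd
    field *= 1.0 + spec.clutter_strength * clutter
    field += spec.noise_sigma * rng.standard_normal((s, s)).astype(np.float32)
    field[~inside] = np.maximum(field[~inside], 0.0) * 0.05
    return np.clip(field, 0.0, None), re


def _place_tumors(spec: PhantomSpec, rng: np.random.Generator,
                  max_tries: int = 500) -> list[tuple[float, float, float]]:
    s = spec.image_size
    ay, ax = spec.head_axes
    cy = cx = (s - 1) / 2.0
    lo, hi = spec.tumor_radius_range
    placed: list[tuple[float, float, float]] = []
    for _ in range(spec.tumor_count):
        for attempt in range(max_tries):
            r = float(rng.uniform(lo, hi))
            # center constrained so the full disk sits inside the head bulk
            py = float(rng.uniform(cy - ay, cy + ay))
            px = float(rng.uniform(cx - ax, cx + ax))
            margin = r + 0.08 * s
            if ((py - cy) / (ay - margin)) ** 2 + ((px - cx) / (ax - margin)) ** 2 > 0.9 ** 2:
                continue
            if any(np.hypot(py - qy, px - qx) < spec.min_separation
                   for qy, qx, _ in placed):
                continue
            placed.append((py, px, r))
            break
        else:
            raise GenerationError(
                f"could not place tumor {len(placed) + 1} after {max_tries} tries")
    return placed


def generate_sample(spec: PhantomSpec, rng: np.random.Generator,
                    sample_id: str = "sample") -> LabeledSample:
    """Generate one labeled phantom image; deterministic for a fixed rng state."""
    field, _ = _head_field(spec, rng)
    tumors = _place_tumors(spec, rng)

    s = spec.image_size
    mask = np.zeros((s, s), dtype=np.uint8)
    if tumors:
        yy, xx = np.mgrid[0:s, 0:s].astype(np.float32)
        # tumors are the dominant scatterers: peak brightness above the
        # 90th percentile of the head background
        inside_vals = field[field > 0]
        floor = np.percentile(inside_vals, 90) if inside_vals.size else 0.5
        for (py, px, r) in tumors:
            amp = float(floor) * 1.8
            sigma = r / np.sqrt(2.0 * np.log(2.0))  # half-maximum at d = r
            d2 = (yy - py) ** 2 + (xx - px) ** 2
            field = field + amp * np.exp(-d2 / (2.0 * sigma ** 2))
            mask[d2 <= r * r] = 1

    peak = float(field.max())
    if peak > 0:
        field = field / peak
    image = intensity_to_rgb(field).astype(np.float32)
    label = LABELS[spec.tumor_count]
    return LabeledSample(image=image, mask=mask, label=label,
                         sample_id=sample_id, tumors=tumors)


def generate_dataset(n_per_class: int = 100, seed: int = 0,
                     spec: PhantomSpec | None = None) -> list[LabeledSample]:
    """Balanced, deterministically shuffled dataset of 3 * n_per_class samples."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    base = spec or PhantomSpec()
    ss = np.random.SeedSequence(seed)
    shuffle_rng = np.random.default_rng(ss.spawn(1)[0])
    children = ss.spawn(3 * n_per_class + 1)[1:]
    samples: list[LabeledSample] = []
    k = 0
    for count, label in enumerate(LABELS):
        cls_spec = replace(base, tumor_count=count)
        for i in range(n_per_class):
            rng = np.random.default_rng(children[k])
            k += 1
            samples.append(generate_sample(cls_spec, rng, f"{label}_{i:03d}"))
    order = shuffle_rng.permutation(len(samples))
    return [samples[i] for i in order]


# --- disk layout -----------------------------------------------------------

def save_dataset(samples: list[LabeledSample], out_dir: str | Path) -> Path:
    """Write paired PNGs (`<id>_img.png`, `<id>_mask.png`) and a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        img8 = np.clip(np.round(s.image * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(img8).save(out_dir / f"{s.sample_id}_img.png")
        Image.fromarray((s.mask * 255).astype(np.uint8), mode="L").save(
            out_dir / f"{s.sample_id}_mask.png")
        rows.append({"id": s.sample_id, "label": s.label,
                     "tumors": json.dumps([[round(v, 3) for v in t] for t in s.tumors])})
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return out_dir


def load_dataset(in_dir: str | Path) -> list[LabeledSample]:
    """Read the layout written by :func:`save_dataset`."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    samples = []
    for row in manifest.itertuples():
        image = np.asarray(Image.open(in_dir / f"{row.id}_img.png"),
                           dtype=np.float32) / 255.0
        mask = (np.asarray(Image.open(in_dir / f"{row.id}_mask.png")) > 127
                ).astype(np.uint8)
        tumors = [tuple(t) for t in json.loads(row.tumors)]
        samples.append(LabeledSample(image=image, mask=mask, label=row.label,
                                     sample_id=row.id, tumors=tumors))
    return samples
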