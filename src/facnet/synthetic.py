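"""Synthetic dermoscopy-like image generator.

Real dermoscopy presents four recurring difficulties for lesion
segmentation: irregular lesion contours with fuzzy boundaries, low contrast
between lesion and surrounding skin, occluding hairs, and bright
immersion-fluid bubbles.  The generator emulates each one with a controlled
knob so the whole pipeline (loading, training, evaluation, ablation) runs
and is testable without any dataset download:

* the lesion is a star-convex blob — a base radius modulated by a
  low-order random cosine series — giving irregular but single-component
  contours;
* the lesion fill is the local skin colour darkened by a factor that scales
  with ``contrast``; ``boundary_blur_sigma`` Gaussian-blurs the blending
  alpha to produce a fuzzy edge;
* dark quadratic-curve strokes emulate hairs, bright rings emulate
  bubbles; additive Gaussian pixel noise tops it off.

The binary ground-truth mask is the *unblurred* blob, so boundary blur
creates genuine label ambiguity just as in real data.  Everything is drawn
from one seeded generator: a config reproduces its dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .data_io import SegmentationSample
from .errors import ConfigurationError

# tone model constants (fractions of full intensity)
SKIN_BASE = 0.75          # mean skin luminance
SHADING_AMP = 0.06        # +/- low-frequency illumination swing
LESION_DARKENING = 0.65   # at contrast=1 the lesion keeps 35% of skin tone
SKIN_TINT = np.array([1.00, 0.82, 0.72])
LESION_TINT = np.array([0.70, 0.55, 0.75])
MAX_HARMONIC = 8          # highest cosine order of the contour modulation
HARMONIC_AMP = 0.22       # total relative radius modulation bound


@dataclass
class SynthConfig:
    n_images: int = 16
    image_size: int = 256
    seed: int = 0
    lesion_radius_range: tuple[float, float] = (0.15, 0.35)
    boundary_blur_sigma: float = 1.5
    contrast: float = 0.5
    hair_count_range: tuple[int, int] = (0, 8)
    bubble_count_range: tuple[int, int] = (0, 5)
    noise_sigma: float = 0.02

    def __post_init__(self):
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi < 0.5):
            raise ConfigurationError(
                f"lesion_radius_range fractions must lie in (0, 0.5), got "
                f"{self.lesion_radius_range}")
        if self.n_images < 1:
            raise ConfigurationError(f"n_images must be >= 1, got {self.n_images}")
        if not 0 < self.contrast <= 1:
            raise ConfigurationError(f"contrast must be in (0, 1], got {self.contrast}")
        # the largest blob (base radius * (1 + modulation)) must fit
        if hi * (1 + HARMONIC_AMP) >= 0.5:
            raise ConfigurationError(
                f"lesion radius fraction {hi} cannot fit the image once the "
                f"contour modulation (up to {HARMONIC_AMP:.0%}) is applied")


def tone_midpoint(contrast: float) -> float:
    """Grey threshold halfway between the brightest possible lesion pixel
    and the darkest possible skin pixel (used by separability checks)."""
    skin_min = (SKIN_BASE - SHADING_AMP) * SKIN_TINT.mean()
    lesion_max = (SKIN_BASE + SHADING_AMP) * (1 - LESION_DARKENING * contrast) \
        * LESION_TINT.mean()
    return 0.5 * (skin_min + lesion_max)


def _smooth_field(rng, size: int, amp: float) -> np.ndarray:
    """Low-frequency multiplicative shading in [-amp, amp]."""
    coarse = rng.standard_normal((4, 4))
    field = ndimage.zoom(coarse, size / 4, order=3)[:size, :size]
    m = np.abs(field).max()
    return field / m * amp if m > 0 else field


def _star_blob(rng, size: int, radius_frac_range) -> np.ndarray:
    """Binary mask of one star-convex harmonic blob, guaranteed in-frame."""
    lo, hi = radius_frac_range
    r0 = rng.uniform(lo, hi) * size
    margin = r0 * (1 + HARMONIC_AMP)
    cy = rng.uniform(margin, size - margin)
    cx = rng.uniform(margin, size - margin)
    orders = np.arange(2, MAX_HARMONIC + 1)
    amps = rng.uniform(0, 1, orders.size)
    amps *= HARMONIC_AMP / max(amps.sum(), 1e-9) * rng.uniform(0.3, 1.0)
    phases = rng.uniform(0, 2 * np.pi, orders.size)
    yy, xx = np.mgrid[0:size, 0:size]
    theta = np.arctan2(yy - cy, xx - cx)
    radius = r0 * (1 + (amps[:, None, None]
                        * np.cos(orders[:, None, None] * theta[None]
                                 + phases[:, None, None])).sum(axis=0))
    dist = np.hypot(yy - cy, xx - cx)
    return (dist <= radius).astype(np.uint8)


def _draw_hair(rng, img: np.ndarray) -> None:
    """One dark quadratic-Bezier stroke, width 1-3 px, blended in place."""
    size = img.shape[1]
    pts = rng.uniform(0, size, (3, 2))
    t = np.linspace(0, 1, 4 * size)[:, None]
    curve = ((1 - t) ** 2 * pts[0] + 2 * (1 - t) * t * pts[1] + t ** 2 * pts[2])
    ij = np.round(curve).astype(int)
    ij = ij[(ij[:, 0] >= 0) & (ij[:, 0] < size) & (ij[:, 1] >= 0) & (ij[:, 1] < size)]
    stroke = np.zeros((size, size), dtype=bool)
    stroke[ij[:, 0], ij[:, 1]] = True
    width = int(rng.integers(1, 4))
    if width > 1:
        stroke = ndimage.binary_dilation(stroke, iterations=width - 1)
    tone = rng.uniform(0.05, 0.25)
    alpha = 0.8
    img[:, stroke] = (1 - alpha) * img[:, stroke] + alpha * tone


def _draw_bubble(rng, img: np.ndarray) -> None:
    """One bright ring (immersion-fluid bubble), blended in place."""
    size = img.shape[1]
    r = rng.uniform(2, size / 10)
    cy, cx = rng.uniform(r, size - r, 2)
    yy, xx = np.mgrid[0:size, 0:size]
    dist = np.hypot(yy - cy, xx - cx)
    ring = np.abs(dist - r) <= 1.0
    img[:, ring] = np.clip(img[:, ring] + rng.uniform(0.15, 0.3), 0, 1)
    interior = dist < r - 1.0
    img[:, interior] = np.clip(img[:, interior] + 0.05, 0, 1)


def generate(config: SynthConfig) -> list[SegmentationSample]:
    """Generate ``config.n_images`` image/mask pairs, reproducibly."""
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    samples = []
    for k in range(config.n_images):
        mask = _star_blob(rng, size, config.lesion_radius_range)
        lum = SKIN_BASE + _smooth_field(rng, size, SHADING_AMP)
        skin = lum[None] * SKIN_TINT[:, None, None]
        lesion = lum[None] * (1 - LESION_DARKENING * config.contrast) \
            * LESION_TINT[:, None, None]
        alpha = mask.astype(np.float64)
        if config.boundary_blur_sigma > 0:
            alpha = ndimage.gaussian_filter(alpha, config.boundary_blur_sigma)
        img = skin * (1 - alpha[None]) + lesion * alpha[None]
        for _ in range(int(rng.integers(config.hair_count_range[0],
                                        config.hair_count_range[1] + 1))):
            _draw_hair(rng, img)
        for _ in range(int(rng.integers(config.bubble_count_range[0],
                                        config.bubble_count_range[1] + 1))):
            _draw_bubble(rng, img)
        if config.noise_sigma > 0:
            img = img + rng.normal(0, config.noise_sigma, img.shape)
        img = np.clip(img, 0, 1).astype(np.float32)
        samples.append(SegmentationSample(
            image=img, mask=mask[None].astype(np.uint8),
            identifier=f"SYN_{config.seed:05d}_{k:05d}"))
    return samples


def write_dataset(samples, root) -> None:
    """Write samples in the ISIC folder layout read by :mod:`facnet.data_io`
    (images/<id>.jpg, masks/<id>_segmentation.png)."""
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    for s in samples:
        img = Image.fromarray(
            (s.image.transpose(1, 2, 0) * 255).round().astype(np.uint8))
        img.save(root / "images" / f"{s.identifier}.jpg", quality=95)
        msk = Image.fromarray((s.mask[0] * 255).astype(np.uint8))
        msk.save(root / "masks" / f"{s.identifier}_segmentation.png")
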