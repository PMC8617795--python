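"""Seeded generator of ultrasound-like images with binary nerve masks.

Real ultrasound nerve images are corrupted by multiplicative speckle,
depth-dependent attenuation, and show the nerve as a hyperechoic (bright)
rim around a darker honeycomb interior. The generator emulates those three
features on a blank canvas:

* a filled rotated ellipse of random size/eccentricity/orientation is the
  nerve mask;
* the noiseless scene is a uniform background with the nerve interior at a
  distinct brightness and a 2-pixel bright rim just inside the boundary,
  everything scaled by a linear top-to-bottom attenuation ramp;
* the scene is multiplied elementwise by unit-mean gamma speckle and
  clipped to [0, 1].

It is a visual surrogate, not a wave-propagation simulation: no acoustic
shadowing, no anisotropy, one nerve per image.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

__all__ = [
    "SyntheticConfig",
    "ImagePair",
    "default_config",
    "generate_image",
    "generate_dataset",
    "save_dataset",
    "load_pair",
    "load_dataset",
]

RIM_WIDTH = 2  # px, hyperechoic rim just inside the nerve boundary


@dataclass(frozen=True)
class SyntheticConfig:
    height: int = 128
    width: int = 128
    nerve_radius_range: tuple = (13, 26)
    nerve_eccentricity_range: tuple = (0.55, 0.95)
    rim_brightness: float = 0.90
    interior_brightness: float = 0.60
    background_brightness: float = 0.35
    speckle_shape: float = 10.0
    attenuation_strength: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise ValueError("image dimensions must be positive")
        lo, hi = self.nerve_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("nerve radius range must satisfy 0 < min <= max")
        if hi >= min(self.height, self.width) / 2:
            raise ValueError("max nerve radius must fit inside the image")
        elo, ehi = self.nerve_eccentricity_range
        if not (0 < elo <= ehi <= 1):
            raise ValueError("eccentricity range must lie in (0, 1]")
        for name in ("rim_brightness", "interior_brightness",
                     "background_brightness"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.speckle_shape > 0:
            raise ValueError("speckle_shape must be positive")
        if not 0 <= self.attenuation_strength <= 1:
            raise ValueError("attenuation_strength must lie in [0, 1]")


@dataclass(frozen=True)
class ImagePair:
    """A grayscale image in [0,1] with its {0,1} nerve mask (same shape)."""

    image: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")


def default_config(size: int = 128, **overrides) -> SyntheticConfig:
    """Default study conditions at a given square canvas size.

    The nerve semi-major axis spans roughly 10-20% of the canvas, keeping
    the foreground fraction well inside (0, 0.5).
    """
    cfg = SyntheticConfig(
        height=size, width=size,
        nerve_radius_range=(max(3, round(size * 0.10)), round(size * 0.20)))
    return replace(cfg, **overrides) if overrides else cfg


def generate_image(config: SyntheticConfig, seed: int) -> ImagePair:
    """Render one seeded image/mask pair under the given conditions."""
    rng = np.random.default_rng(seed)
    h, w = config.height, config.width

    r_lo, r_hi = config.nerve_radius_range
    a = rng.uniform(r_lo, r_hi)                       # semi-major axis
    b = a * rng.uniform(*config.nerve_eccentricity_range)
    angle = rng.uniform(0, np.pi)
    margin = a + 2
    cy = rng.uniform(margin, h - margin)
    cx = rng.uniform(margin, w - margin)

    mask = np.zeros((h, w), dtype=np.uint8)
    rr, cc = draw_ellipse(cy, cx, a, b, shape=(h, w), rotation=angle)
    mask[rr, cc] = 1

    interior = ndimage.binary_erosion(mask, iterations=RIM_WIDTH)
    rim = mask.astype(bool) & ~interior

    scene = np.full((h, w), config.background_brightness)
    scene[interior] = config.interior_brightness
    scene[rim] = config.rim_brightness

    atten = 1.0 - config.attenuation_strength * (
        np.arange(h) / max(h - 1, 1))
    scene = scene * atten[:, None]

    if math.isinf(config.speckle_shape):
        speckle = np.ones((h, w))
    else:
        k = config.speckle_shape
        speckle = rng.gamma(shape=k, scale=1.0 / k, size=(h, w))
    image = np.clip(scene * speckle, 0.0, 1.0)
    return ImagePair(image=image, mask=mask)


def generate_dataset(n: int, config: SyntheticConfig):
    """Generate n pairs plus 70/10/20 train/validation/test split labels.

    Per-pair seeds and the split assignment both derive from ``config.seed``,
    so two calls with the same config agree exactly. Split sizes are
    floor(0.7 n) / floor(0.1 n) / remainder, disjoint by construction.
    """
    if n < 10:
        raise ValueError("need n >= 10 so every split is non-empty")
    seeds = np.random.SeedSequence(config.seed).spawn(n + 1)
    pairs = [generate_image(config, s) for s in seeds[:n]]
    order = np.random.default_rng(seeds[n]).permutation(n)
    n_train, n_val = int(0.7 * n), int(0.1 * n)
    splits = np.empty(n, dtype=object)
    splits[order[:n_train]] = "train"
    splits[order[n_train:n_train + n_val]] = "val"
    splits[order[n_train + n_val:]] = "test"
    return pairs, list(splits)


def _to_u8(arr: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(arr, dtype=float) * 255).astype(np.uint8)


def save_dataset(pairs, splits, outdir: str) -> str:
    """Write pairs as 8-bit grayscale PNGs plus a manifest CSV; returns its path."""
    os.makedirs(outdir, exist_ok=True)
    rows = []
    for i, (pair, split) in enumerate(zip(pairs, splits), start=1):
        img_name, msk_name = f"img_{i:04d}.png", f"msk_{i:04d}.png"
        iio.imwrite(os.path.join(outdir, img_name), _to_u8(pair.image))
        iio.imwrite(os.path.join(outdir, msk_name), _to_u8(pair.mask))
        rows.append({"image": img_name, "mask": msk_name, "split": split})
    manifest = os.path.join(outdir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_pair(image_path: str, mask_path: str) -> ImagePair:
    """Read any same-shape grayscale image/mask pair (PNG or TIFF)."""
    img = np.asarray(iio.imread(image_path), dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    if img.max() > 1:
        img = img / 255.0
    msk = np.asarray(iio.imread(mask_path))
    if msk.ndim == 3:
        msk = msk.max(axis=-1)
    msk = (msk > msk.max() / 2 if msk.max() > 1 else msk >= 0.5).astype(np.uint8)
    return ImagePair(image=np.clip(img, 0, 1), mask=msk)


def load_dataset(directory: str):
    """Read a dataset written by :func:`save_dataset` (or hand-made manifest)."""
    manifest = pd.read_csv(os.path.join(directory, "manifest.csv"))
    pairs = [load_pair(os.path.join(directory, r.image),
                       os.path.join(directory, r.mask))
             for r in manifest.itertuples()]
    return pairs, list(manifest["split"])
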