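"""Seeded synthetic texture images emulating the three diagnostic classes.

No public MRI dataset accompanies the method, so the benchmark is a
synthetic generator whose three classes differ in exactly the texture
properties the pipeline measures:

* ``normal`` — a smooth, low-variance background (a large-scale random
  field) with no lesion; the ground-truth mask is empty.
* ``benign`` — the same background plus one bright disc carrying a regular
  sinusoidal internal texture; the mask is the disc.
* ``malignant`` — a bright region with a randomly perturbed (star-shaped)
  boundary and salt-like high-contrast internal speckle; the mask is the
  region.

Additive Gaussian pixel noise is applied everywhere.  The texture
amplitudes are chosen so the headline grey-level co-occurrence statistics
(contrast, energy, entropy, autocorrelation) are ordered across classes:
malignant images have the highest contrast and entropy, normal images the
lowest.  Everything is deterministic under the master seed; per-item seeds
are spawned from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DataError
from .image_io import GreyImage
from .segmentation import BinaryMask

__all__ = ["CLASS_LABELS", "SyntheticSpec", "make_image", "make_dataset", "make_feature_clusters"]

CLASS_LABELS: tuple[str, ...] = ("normal", "benign", "malignant")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters (intensities on the 0..255 grey scale).

    size                  : (height, width) in pixels.
    blob_radius_range     : min/max lesion radius in pixels.
    background_mean       : mean background intensity.
    background_sigma      : amplitude of the smooth background field.
    blob_mean             : mean lesion intensity.
    benign_texture_period : wavelength (pixels) of the benign sinusoid.
    benign_texture_amp    : amplitude of the benign sinusoid.
    malignant_contrast    : amplitude of the malignant speckle.
    noise_sigma           : std of the additive Gaussian pixel noise.
    """

    size: tuple[int, int] = (256, 256)
    classes: tuple[str, ...] = CLASS_LABELS
    blob_radius_range: tuple[float, float] = (40.0, 64.0)
    background_mean: float = 60.0
    background_sigma: float = 6.0
    blob_mean: float = 170.0
    benign_texture_period: float = 8.0
    benign_texture_amp: float = 25.0
    malignant_contrast: float = 80.0
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.size
        rmin, rmax = self.blob_radius_range
        if h < 8 or w < 8:
            raise DataError(f"image size {self.size} too small")
        if not 0 < rmin <= rmax:
            raise DataError(f"invalid radius range {self.blob_radius_range}")
        if 2 * rmax >= min(h, w):
            raise DataError("lesion radius does not fit inside the image")
        for name in ("background_sigma", "benign_texture_amp", "malignant_contrast", "noise_sigma"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")

    @classmethod
    def for_size(cls, side: int, **overrides) -> "SyntheticSpec":
        """Spec scaled to a square image of the given side length."""
        return cls(
            size=(side, side),
            blob_radius_range=(0.16 * side, 0.25 * side),
            **overrides,
        )


def _background(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.size
    field = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=min(h, w) / 8, mode="reflect")
    std = field.std()
    if std > 0 and spec.background_sigma > 0:
        field *= spec.background_sigma / std
    else:
        field[:] = 0.0
    return spec.background_mean + field


def _lesion_geometry(spec: SyntheticSpec, rng: np.random.Generator, irregular: bool):
    h, w = spec.size
    cy = h / 2 + rng.uniform(-0.08, 0.08) * h
    cx = w / 2 + rng.uniform(-0.08, 0.08) * w
    r0 = rng.uniform(*spec.blob_radius_range)
    yy, xx = np.indices((h, w))
    dy, dx = yy - cy, xx - cx
    dist = np.hypot(dy, dx)
    if not irregular:
        return dist <= r0
    phi = np.arctan2(dy, dx)
    radius = np.full((h, w), r0)
    for k in range(2, 6):
        amp = rng.uniform(0.03, 0.12)
        phase = rng.uniform(0, 2 * np.pi)
        radius += r0 * amp * np.cos(k * phi + phase)
    return dist <= radius


def make_image(
    label: str, spec: SyntheticSpec | None = None, seed: int | None = None
) -> tuple[GreyImage, BinaryMask]:
    """Generate one image and its ground-truth lesion mask, deterministically."""
    spec = spec or SyntheticSpec()
    if label not in spec.classes:
        raise DataError(f"unknown class label {label!r}; expected one of {spec.classes}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    h, w = spec.size
    img = _background(spec, rng)
    mask = np.zeros((h, w), dtype=np.uint8)

    if label == "benign":
        inside = _lesion_geometry(spec, rng, irregular=False)
        theta = rng.uniform(0, np.pi)
        yy, xx = np.indices((h, w))
        wave = np.sin(2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / spec.benign_texture_period)
        img[inside] = spec.blob_mean + spec.benign_texture_amp * wave[inside]
        mask[inside] = 1
    elif label == "malignant":
        inside = _lesion_geometry(spec, rng, irregular=True)
        # salt-like ternary speckle with a 2-pixel correlation length, so the
        # irregular texture lives above the smoothing scale of preprocessing
        coarse = rng.choice([-1.0, 0.0, 1.0], size=((h + 1) // 2, (w + 1) // 2), p=[0.25, 0.5, 0.25])
        speckle = np.repeat(np.repeat(coarse, 2, axis=0), 2, axis=1)[:h, :w]
        img[inside] = spec.blob_mean + spec.malignant_contrast * speckle[inside]
        mask[inside] = 1

    if spec.noise_sigma > 0:
        img = img + rng.normal(0, spec.noise_sigma, size=(h, w))
    px = np.clip(np.rint(img), 0, 255).astype(np.int64)
    return GreyImage(px, levels=256), BinaryMask(mask)


def make_dataset(
    n_per_class: int, spec: SyntheticSpec | None = None, seed: int = 0
) -> list[tuple[GreyImage, BinaryMask, str]]:
    """Balanced dataset of ``3 * n_per_class`` items; per-item seeds are
    spawned deterministically from the master seed."""
    spec = spec or SyntheticSpec()
    if n_per_class < 0:
        raise DataError("n_per_class must be >= 0")
    children = np.random.SeedSequence(seed).spawn(len(spec.classes) * n_per_class)
    out = []
    i = 0
    for label in spec.classes:
        for _ in range(n_per_class):
            item_seed = int(children[i].generate_state(1)[0] % (2**31))
            image, mask = make_image(label, spec, seed=item_seed)
            out.append((image, mask, label))
            i += 1
    return out


def make_feature_clusters(
    n_per_class: int,
    separation: float,
    dims: int = 14,
    seed: int = 0,
    classes: tuple[str, ...] = CLASS_LABELS,
) -> list[tuple[np.ndarray, str]]:
    """Three unit-variance isotropic Gaussian clusters in feature space.

    Cluster centers form an equilateral triangle with pairwise distance
    ``separation`` (in units of the within-cluster standard deviation).
    """
    if dims < 2:
        raise DataError("dims must be >= 2 to place three distinct centers")
    rng = np.random.default_rng(seed)
    s = float(separation)
    centers = np.zeros((3, dims))
    centers[1, 0] = s
    centers[2, 0] = s / 2
    centers[2, 1] = s * np.sqrt(3) / 2
    out = []
    for c, label in enumerate(classes):
        X = rng.normal(size=(n_per_class, dims)) + centers[c]
        out.extend((X[i], label) for i in range(n_per_class))
    return out
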