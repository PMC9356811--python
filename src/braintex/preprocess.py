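"""Noise removal and contrast enhancement ahead of feature extraction.

The enhancement chain is Gaussian smoothing (noise suppression) followed by
unsharp masking (contrast boost between normal tissue and lesion), the order
being configurable.  Both steps keep the image on its original integer
intensity grid: results are computed in floating point, rounded to nearest,
and clipped to ``0..levels-1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DataError
from .image_io import GreyImage

__all__ = ["PreprocessConfig", "gaussian_smooth", "sharpen", "apply_preprocess"]

#: Gaussian kernels are truncated at 4 standard deviations.
GAUSSIAN_TRUNCATE = 4.0


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the enhancement chain.

    gaussian_sigma : smoothing scale in pixels (> 0 when 'smooth' enabled).
    sharpen_amount : unsharp blend weight (0 disables sharpening exactly).
    sharpen_sigma  : scale of the blur subtracted by unsharp masking.
    steps          : ordered subset of {"smooth", "sharpen"}.
    """

    gaussian_sigma: float = 1.0
    sharpen_amount: float = 1.0
    sharpen_sigma: float = 1.0
    steps: tuple[str, ...] = ("smooth", "sharpen")

    def __post_init__(self) -> None:
        unknown = set(self.steps) - {"smooth", "sharpen"}
        if unknown:
            raise DataError(f"unknown preprocessing steps {sorted(unknown)}")
        if "smooth" in self.steps and self.gaussian_sigma <= 0:
            raise DataError("gaussian_sigma must be > 0 when smoothing is enabled")
        if self.sharpen_amount < 0:
            raise DataError("sharpen_amount must be >= 0")


def _to_grey(float_px: np.ndarray, levels: int) -> GreyImage:
    out = np.clip(np.rint(float_px), 0, levels - 1).astype(np.int64)
    return GreyImage(out, levels=levels)


def _smooth_float(px: np.ndarray, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(
        px.astype(np.float64), sigma=sigma, mode="reflect", truncate=GAUSSIAN_TRUNCATE
    )


def gaussian_smooth(image: GreyImage, sigma: float) -> GreyImage:
    """Discrete Gaussian convolution with reflective borders.

    The kernel is truncated at 4*sigma; the mean intensity is preserved up
    to integer rounding, and the intensity variance never increases.
    """
    if sigma <= 0:
        raise DataError(f"sigma must be > 0, got {sigma}")
    return _to_grey(_smooth_float(image.pixels, sigma), image.levels)


def sharpen(image: GreyImage, amount: float, sigma: float = 1.0) -> GreyImage:
    """Unsharp masking: ``out = clip(x + amount * (x - blur(x, sigma)))``.

    ``amount=0`` is an exact identity.
    """
    if amount < 0:
        raise DataError(f"amount must be >= 0, got {amount}")
    if amount == 0:
        return image
    px = image.pixels.astype(np.float64)
    out = px + amount * (px - _smooth_float(px, sigma))
    return _to_grey(out, image.levels)


def apply_preprocess(image: GreyImage, cfg: PreprocessConfig | None = None) -> GreyImage:
    """Run the configured enhancement steps in order."""
    cfg = cfg or PreprocessConfig()
    out = image
    for step in cfg.steps:
        if step == "smooth":
            out = gaussian_smooth(out, cfg.gaussian_sigma)
        else:
            out = sharpen(out, cfg.sharpen_amount, cfg.sharpen_sigma)
    return out
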