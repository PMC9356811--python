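"""Grey-scale image I/O, quantization and tabular output.

Conventions used throughout the package
---------------------------------------
* Images are 2-D integer grids in (row, col) order, 0-based, row 0 at top.
* Intensities lie in ``0 .. levels-1``; 8-bit inputs have ``levels=256``.
* Color PNGs are converted to grey with integer Rec. 601 luminance,
  ``(299*R + 587*G + 114*B + 500) // 1000``.
* 16-bit TIFFs are rescaled to 0..255 by exact integer rounding,
  ``(v*255 + 32767) // 65535``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .errors import DataError, FormatError

__all__ = [
    "GreyImage",
    "read_image",
    "write_image",
    "quantize",
    "write_feature_table",
    "read_feature_table",
    "FEATURE_NAMES",
]

#: Fixed order of the 14 texture features; the CSV header and every
#: TextureFeatureVector follow this order.
FEATURE_NAMES: tuple[str, ...] = (
    "autocorrelation",
    "contrast",
    "correlation",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "maximum_probability",
    "mean",
    "variance",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_entropy",
)


@dataclass(frozen=True)
class GreyImage:
    """A 2-D grey-scale image with a known number of grey levels.

    Parameters
    ----------
    pixels :
        2-D array of non-negative integers, row-major, row 0 at top.
    levels :
        Number of grey levels G; every pixel satisfies ``0 <= p < levels``.
    """

    pixels: np.ndarray = field(repr=False)
    levels: int = 256

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise DataError(f"image must be a non-empty 2-D grid, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise DataError(f"image intensities must be integers, got dtype {px.dtype}")
        if self.levels < 2:
            raise DataError(f"levels must be >= 2, got {self.levels}")
        if px.min() < 0 or px.max() >= self.levels:
            raise DataError(
                f"intensities must lie in [0, {self.levels - 1}], "
                f"found range [{px.min()}, {px.max()}]"
            )
        px = np.ascontiguousarray(px)
        px.setflags(write=False)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def read_image(path: str | Path) -> GreyImage:
    """Read a PNG or TIFF file as an 8-bit grey image (``levels=256``).

    Color images are converted by integer Rec. 601 luminance; 16-bit
    images are rescaled to 0..255 with exact integer rounding.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            arr = np.asarray(im)
    except UnidentifiedImageError as exc:
        raise FormatError(f"cannot decode {path}: {exc}") from exc

    if mode == "L":
        px = arr.astype(np.int64)
    elif mode in ("I", "I;16", "I;16B", "I;16L"):
        v = arr.astype(np.int64)
        px = (v * 255 + 32767) // 65535
    elif mode in ("RGB", "RGBA"):
        rgb = arr[..., :3].astype(np.int64)
        px = (299 * rgb[..., 0] + 587 * rgb[..., 1] + 114 * rgb[..., 2] + 500) // 1000
    elif mode == "P":
        with Image.open(path) as im:
            grey = np.asarray(im.convert("RGB")).astype(np.int64)
        px = (299 * grey[..., 0] + 587 * grey[..., 1] + 114 * grey[..., 2] + 500) // 1000
    else:
        raise FormatError(f"unsupported image mode {mode!r} in {path}")
    return GreyImage(np.clip(px, 0, 255).astype(np.int64), levels=256)


def write_image(image: GreyImage, path: str | Path) -> None:
    """Write an image as 8-bit PNG/TIFF (intensities must fit in 0..255)."""
    if image.levels > 256:
        raise DataError("only images with <= 256 levels can be written as 8-bit")
    Image.fromarray(image.pixels.astype(np.uint8), mode="L").save(Path(path))


def quantize(image: GreyImage, levels: int, stretch: bool = False) -> GreyImage:
    """Reduce an image to ``levels`` grey levels by uniform binning.

    By default the bins tile the full representable range ``0..image.levels-1``
    (intensity ``k`` maps to ``k * levels // image.levels``) so features are
    comparable across images.  With ``stretch=True`` the bins tile the image's
    own min-max range instead.  The mapping is monotone non-decreasing and
    idempotent at a fixed level count.
    """
    if levels < 2:
        raise DataError(f"levels must be >= 2, got {levels}")
    if levels > image.levels:
        raise DataError(f"cannot quantize {image.levels}-level image up to {levels} levels")
    px = image.pixels.astype(np.int64)
    if stretch:
        lo, hi = int(px.min()), int(px.max())
        if hi == lo:
            return GreyImage(np.zeros_like(px), levels=levels)
        q = (px - lo) * levels // (hi - lo + 1)
    else:
        q = px * levels // image.levels
    return GreyImage(np.clip(q, 0, levels - 1), levels=levels)


def write_feature_table(rows, path: str | Path) -> None:
    """Write ``(image_id, label, feature_vector)`` rows to CSV.

    The header is ``image_id,label`` followed by the 14 fixed feature names;
    values round-trip at full float precision.
    """
    records = []
    for image_id, label, vec in rows:
        values = list(vec)
        if len(values) != len(FEATURE_NAMES):
            raise DataError(
                f"feature vector for {image_id!r} has {len(values)} values, "
                f"expected {len(FEATURE_NAMES)}"
            )
        records.append({"image_id": image_id, "label": label, **dict(zip(FEATURE_NAMES, values))})
    df = pd.DataFrame(records, columns=["image_id", "label", *FEATURE_NAMES])
    df.to_csv(Path(path), index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read back a feature CSV written by :func:`write_feature_table`."""
    df = pd.read_csv(Path(path), float_precision="round_trip")
    missing = [c for c in ("image_id", "label", *FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise FormatError(f"feature table {path} is missing columns {missing}")
    return df
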