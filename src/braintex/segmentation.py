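"""Threshold segmentation with morphological clean-up.

The tumor mask is produced by global intensity thresholding (a pixel is
foreground iff its intensity strictly exceeds the threshold), followed by a
morphological closing with a 3x3 square structuring element, hole filling,
and optionally keeping only the largest connected component.  When no
threshold is supplied, Otsu's criterion (maximum between-class variance,
ties broken toward the smallest threshold) chooses one automatically; an
additional separability guard declares the image tumor-free when the
intensity histogram is essentially unimodal.

Connectivity is 4-connectivity throughout (hole filling, component
labeling).  For morphology, pixels outside the image are background for
dilation and foreground for erosion (so erosion/dilation are exact
complements under mask complementation and closing is extensive); linear
filters in :mod:`braintex.preprocess` use reflective borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DataError, DegenerateInputError
from .image_io import GreyImage

__all__ = [
    "BinaryMask",
    "SegmentationConfig",
    "SegmentationResult",
    "SQUARE_3X3",
    "global_threshold",
    "otsu_threshold",
    "dilate",
    "erode",
    "fill_holes",
    "largest_component",
    "edge_mixture_map",
    "segment_tumor",
]

#: The default structuring element: a 3x3 square of ones.
SQUARE_3X3 = np.ones((3, 3), dtype=np.int64)

#: 4-connectivity structure for labeling and hole filling.
_CONN4 = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class BinaryMask:
    """A 2-D grid of {0, 1}: 0 = background (black), 1 = foreground (white)."""

    pixels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise DataError(f"mask must be a non-empty 2-D grid, got shape {px.shape}")
        px = px.astype(np.uint8)
        if not np.isin(px, (0, 1)).all():
            raise DataError("mask values must be exactly 0 or 1")
        px = np.ascontiguousarray(px)
        px.setflags(write=False)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def foreground_count(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class SegmentationConfig:
    """Knobs of :func:`segment_tumor`.

    threshold         : explicit intensity cut, or None for automatic (Otsu).
    keep_largest      : keep only the largest 4-connected foreground component.
    min_separability  : in automatic mode, minimum Otsu effectiveness ratio
                        (between-class / total variance, in [0, 1]) below which
                        the image is declared tumor-free and the mask is empty.
                        Unimodal intensity distributions stay below ~0.75 (the
                        uniform-density value; a Gaussian gives ~0.64), while
                        two separated modes push the ratio toward 1, so 0.8
                        separates "background only" from "lesion present".
    """

    threshold: int | None = None
    keep_largest: bool = True
    min_separability: float = 0.8


@dataclass(frozen=True)
class SegmentationResult:
    """All intermediate masks of the segmentation chain, plus the threshold."""

    threshold: int
    mask_threshold: BinaryMask
    mask_morph: BinaryMask
    mask_filled: BinaryMask
    final: BinaryMask


def global_threshold(image: GreyImage, t: int) -> BinaryMask:
    """Foreground (1) iff intensity strictly exceeds ``t``."""
    if not 0 <= t < image.levels:
        raise DataError(f"threshold {t} outside [0, {image.levels - 1}]")
    return BinaryMask((image.pixels > t).astype(np.uint8))


def _otsu_from_hist(hist: np.ndarray) -> tuple[int, float]:
    """Exhaustive Otsu scan on a histogram.

    Returns ``(threshold, effectiveness)`` where threshold maximizes the
    between-class variance of the split {<= t} vs {> t} (smallest argmax on
    ties) and effectiveness is between-class / total variance at the optimum.
    """
    levels = np.arange(hist.size, dtype=np.float64)
    n = hist.sum()
    w0 = np.cumsum(hist)[:-1]  # candidate t = 0 .. L-2
    w1 = n - w0
    s0 = np.cumsum(hist * levels)[:-1]
    mu_total = (hist * levels).sum() / n
    valid = (w0 > 0) & (w1 > 0)
    bcv = np.zeros(hist.size - 1)
    mu0 = np.divide(s0, w0, out=np.zeros_like(bcv), where=valid)
    mu1 = np.divide((hist * levels).sum() - s0, w1, out=np.zeros_like(bcv), where=valid)
    bcv[valid] = (w0[valid] / n) * (w1[valid] / n) * (mu0[valid] - mu1[valid]) ** 2
    t = int(np.argmax(bcv))
    total_var = float((hist * (levels - mu_total) ** 2).sum() / n)
    eff = float(bcv[t] / total_var) if total_var > 0 else 0.0
    return t, eff


def otsu_threshold(image: GreyImage) -> int:
    """Threshold maximizing between-class variance over all candidate levels."""
    px = image.pixels
    if px.min() == px.max():
        raise DegenerateInputError("Otsu threshold is undefined for a constant image")
    hist = np.bincount(px.ravel(), minlength=image.levels).astype(np.float64)
    t, _ = _otsu_from_hist(hist)
    return t


def _shift(px: np.ndarray, dr: int, dc: int, pad: int = 0) -> np.ndarray:
    """Shift a binary array by (dr, dc), filling vacated cells with ``pad``."""
    H, W = px.shape
    out = np.full_like(px, pad)
    rs = slice(max(0, dr), min(H, H + dr))
    cs = slice(max(0, dc), min(W, W + dc))
    rsrc = slice(max(0, -dr), min(H, H - dr))
    csrc = slice(max(0, -dc), min(W, W - dc))
    out[rs, cs] = px[rsrc, csrc]
    return out


def _se_offsets(se: np.ndarray) -> list[tuple[int, int]]:
    se = np.asarray(se)
    if se.ndim != 2 or se.size == 0 or not se.any():
        raise DataError("structuring element must be a non-empty 2-D binary grid")
    orow, ocol = se.shape[0] // 2, se.shape[1] // 2
    return [(int(r - orow), int(c - ocol)) for r, c in zip(*np.nonzero(se))]


def dilate(mask: BinaryMask, se: np.ndarray = SQUARE_3X3) -> BinaryMask:
    """Binary dilation: output(p) = 1 iff the reflected SE at p hits foreground.

    Equivalently the union of the mask shifted by every SE offset; borders
    are zero-padded.
    """
    px = mask.pixels.astype(bool)
    out = np.zeros_like(px)
    for dr, dc in _se_offsets(se):
        out |= _shift(px, dr, dc)
    return BinaryMask(out.astype(np.uint8))


def erode(mask: BinaryMask, se: np.ndarray = SQUARE_3X3) -> BinaryMask:
    """Binary erosion: output(p) = 1 iff the SE at p fits inside the foreground.

    Pixels outside the image count as foreground for erosion (and as
    background for dilation) — the convention under which complement
    duality ``erode(m) = not dilate(not m)`` and closing extensivity hold
    exactly on a finite grid.
    """
    px = mask.pixels
    out = np.ones_like(px, dtype=bool)
    for dr, dc in _se_offsets(se):
        out &= _shift(px, -dr, -dc, pad=1).astype(bool)
    return BinaryMask(out.astype(np.uint8))


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Set to foreground every background region not 4-connected to the border."""
    filled = ndimage.binary_fill_holes(mask.pixels.astype(bool), structure=_CONN4)
    return BinaryMask(filled.astype(np.uint8))


def largest_component(mask: BinaryMask) -> BinaryMask:
    """Keep only the largest 4-connected foreground component (empty stays empty)."""
    labels, n = ndimage.label(mask.pixels, structure=_CONN4)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())[1:]
    keep = int(np.argmax(sizes)) + 1
    return BinaryMask((labels == keep).astype(np.uint8))


# Directional 3x3 gradient kernels (Sobel-style).  "Vertical" responds to
# vertical edges (horizontal intensity change), and so on.
_K_VERTICAL = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
_K_HORIZONTAL = _K_VERTICAL.T
_K_DIAG1 = np.array([[0, 1, 2], [-1, 0, 1], [-2, -1, 0]], dtype=np.float64)
_K_DIAG2 = np.array([[2, 1, 0], [1, 0, -1], [0, -1, -2]], dtype=np.float64)


def _edge_binary(px: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Threshold one directional gradient-magnitude map with Otsu."""
    resp = np.abs(ndimage.correlate(px.astype(np.float64), kernel, mode="reflect"))
    peak = resp.max()
    if peak <= 0:
        return np.zeros_like(resp, dtype=bool)
    q = np.minimum((resp / peak * 256).astype(np.int64), 255)
    if q.min() == q.max():
        return np.zeros_like(resp, dtype=bool)
    t, _ = _otsu_from_hist(np.bincount(q.ravel(), minlength=256).astype(np.float64))
    return q > t

def edge_mixture_map(image: GreyImage) -> BinaryMask:
    """Mark regions where vertical, horizontal and diagonal edges intermix.

    Each directional gradient-magnitude map is binarized with Otsu and
    dilated with the 3x3 square; a pixel is foreground iff all three edge
    types are present in its dilated neighborhood.  Text-like or
    checkerboard-like patches light up; isolated straight edges do not.
    """
    if image.height < 3 or image.width < 3:
        raise DegenerateInputError("edge analysis needs an image of at least 3x3")
    px = image.pixels
    vert = _edge_binary(px, _K_VERTICAL)
    horiz = _edge_binary(px, _K_HORIZONTAL)
    diag = _edge_binary(px, _K_DIAG1) | _edge_binary(px, _K_DIAG2)
    mixed = np.ones(px.shape, dtype=bool)
    for m in (vert, horiz, diag):
        mixed &= dilate(BinaryMask(m.astype(np.uint8))).pixels.astype(bool)
    return BinaryMask(mixed.astype(np.uint8))


def segment_tumor(image: GreyImage, cfg: SegmentationConfig | None = None) -> SegmentationResult:
    """Full segmentation chain: threshold, closing, hole filling, selection.

    With an automatic threshold, the separability guard returns an empty
    mask when Otsu's effectiveness ratio falls below
    ``cfg.min_separability`` (an essentially unimodal, i.e. tumor-free,
    image).  All intermediate masks are retained in the result.
    """
    cfg = cfg or SegmentationConfig()
    px = image.pixels
    empty = BinaryMask(np.zeros(px.shape, dtype=np.uint8))
    if cfg.threshold is not None:
        t = int(cfg.threshold)
        if not 0 <= t < image.levels:
            raise DataError(f"threshold {t} outside [0, {image.levels - 1}]")
    else:
        if px.min() == px.max():
            t = int(px.min())
            return SegmentationResult(t, empty, empty, empty, empty)
        hist = np.bincount(px.ravel(), minlength=image.levels).astype(np.float64)
        t, eff = _otsu_from_hist(hist)
        if eff < cfg.min_separability:
            mask_t = global_threshold(image, t)
            return SegmentationResult(t, mask_t, empty, empty, empty)
    mask_t = global_threshold(image, t)
    mask_morph = erode(dilate(mask_t, SQUARE_3X3), SQUARE_3X3)  # closing
    mask_filled = fill_holes(mask_morph)
    final = largest_component(mask_filled) if cfg.keep_largest else mask_filled
    return SegmentationResult(t, mask_t, mask_morph, mask_filled, final)
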