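"""Grey-level co-occurrence matrices and the 14-feature texture vector.

A co-occurrence matrix for offset ``(drow, dcol)`` counts, over every pixel
``p`` for which ``p + offset`` is still inside the image, the pair of
intensities ``(I[p], I[p + offset])``.  Four orientations are supported
(0, 45, 90, 135 degrees at distance ``d``), plus their element-wise average
as a fifth, approximately rotation-invariant matrix.  With ``symmetric=True``
(the default) every pair is also counted in the reversed direction, so the
matrix is its own transpose.

From the normalized matrix ``p(a, b)`` the classical Haralick-style texture
statistics are computed.  The feature vector holds exactly the 14 quantities
listed in :data:`braintex.image_io.FEATURE_NAMES`: autocorrelation
(sum a*b*p), contrast (sum (a-b)^2 p), correlation, dissimilarity
(sum |a-b| p), energy / angular second moment (sum p^2), entropy
(-sum p ln p, natural log), homogeneity / inverse difference moment
(sum p / (1 + (a-b)^2)), maximum probability, the marginal mean and the
joint variance about it, and the sum/difference statistics (sum average,
sum variance, sum entropy, difference entropy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .errors import DataError, DegenerateInputError
from .image_io import FEATURE_NAMES, GreyImage, quantize

__all__ = [
    "ANGLES",
    "CooccurrenceMatrix",
    "MarginalStats",
    "TextureFeatureVector",
    "cooccurrence",
    "average_matrix",
    "cooccurrence_stack",
    "marginal_stats",
    "texture_features",
    "extract",
]

log = logging.getLogger(__name__)

#: Supported orientations in degrees and their (drow, dcol) unit offsets.
#: Rows grow downward, so 45/135 degrees point up-right / up-left.
ANGLES: tuple[int, ...] = (0, 45, 90, 135)
_UNIT_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """G x G pair-count matrix with normalized probabilities.

    ``angle`` is one of 0/45/90/135 or the string ``"avg"`` for the
    orientation-averaged matrix (whose ``counts`` are the summed raw counts
    of its four constituents).
    """

    counts: np.ndarray = field(repr=False)
    probs: np.ndarray = field(repr=False)
    offset: tuple[int, int] | None
    distance: int
    angle: int | str
    symmetric: bool
    levels: int

    def __post_init__(self) -> None:
        c, p = np.asarray(self.counts), np.asarray(self.probs)
        if c.shape != (self.levels, self.levels) or p.shape != c.shape:
            raise DataError("counts/probs must be G x G with G = levels")
        if c.min() < 0:
            raise DataError("pair counts must be non-negative")
        total = p.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise DataError(f"probabilities must sum to 1, got {total}")


class MarginalStats(NamedTuple):
    """Probability-weighted moments of the row/column marginals."""

    mean_row: float
    mean_col: float
    var_row: float
    var_col: float


class TextureFeatureVector(NamedTuple):
    """The 14 texture statistics, in the fixed package-wide order."""

    autocorrelation: float
    contrast: float
    correlation: float
    dissimilarity: float
    energy: float
    entropy: float
    homogeneity: float
    maximum_probability: float
    mean: float
    variance: float
    sum_average: float
    sum_variance: float
    sum_entropy: float
    difference_entropy: float


assert TextureFeatureVector._fields == FEATURE_NAMES


def cooccurrence(
    image: GreyImage,
    distance: int = 1,
    angle: int = 0,
    symmetric: bool = True,
) -> CooccurrenceMatrix:
    """Build the co-occurrence matrix for one orientation.

    ``counts[a, b]`` is the number of pixel pairs ``(p, p + offset)`` with
    intensities ``(a, b)``; with ``symmetric=True`` the reversed pairs are
    added too, making the matrix symmetric.
    """
    if angle not in _UNIT_OFFSETS:
        raise DataError(f"angle must be one of {ANGLES}, got {angle}")
    if distance < 1:
        raise DataError(f"distance must be >= 1, got {distance}")
    G = image.levels
    dr, dc = (distance * o for o in _UNIT_OFFSETS[angle])
    px = image.pixels
    H, W = px.shape
    r0, r1 = max(0, -dr), H - max(0, dr)
    c0, c1 = max(0, -dc), W - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        raise DegenerateInputError(
            f"offset ({dr}, {dc}) admits no pixel pairs in a {H}x{W} image"
        )
    a = px[r0:r1, c0:c1].ravel()
    b = px[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    counts = np.bincount(a * G + b, minlength=G * G).reshape(G, G)
    if symmetric:
        counts = counts + counts.T
    probs = counts / counts.sum()
    return CooccurrenceMatrix(
        counts=counts,
        probs=probs,
        offset=(dr, dc),
        distance=distance,
        angle=angle,
        symmetric=symmetric,
        levels=G,
    )


def average_matrix(mats: Iterable[CooccurrenceMatrix]) -> CooccurrenceMatrix:
    """Element-wise mean of the four orientation matrices (the fifth matrix)."""
    mats = list(mats)
    if len(mats) != 4:
        raise DataError(f"expected the 4 orientation matrices, got {len(mats)}")
    ref = mats[0]
    for m in mats[1:]:
        if m.levels != ref.levels or m.distance != ref.distance or m.symmetric != ref.symmetric:
            raise DataError("matrices to average must share levels, distance and symmetry")
    probs = np.mean([m.probs for m in mats], axis=0)
    counts = np.sum([m.counts for m in mats], axis=0)
    return CooccurrenceMatrix(
        counts=counts,
        probs=probs,
        offset=None,
        distance=ref.distance,
        angle="avg",
        symmetric=ref.symmetric,
        levels=ref.levels,
    )


def cooccurrence_stack(
    image: GreyImage, distance: int = 1, symmetric: bool = True
) -> dict[int | str, CooccurrenceMatrix]:
    """The four orientation matrices plus their average, keyed by angle."""
    mats = {a: cooccurrence(image, distance, a, symmetric) for a in ANGLES}
    mats["avg"] = average_matrix([mats[a] for a in ANGLES])
    return mats


def marginal_stats(P: CooccurrenceMatrix) -> MarginalStats:
    """Means and variances of the row/column marginal distributions."""
    p = P.probs
    if p.sum() <= 0:
        raise DegenerateInputError("all-zero co-occurrence matrix")
    levels = np.arange(P.levels, dtype=np.float64)
    p_row = p.sum(axis=1)
    p_col = p.sum(axis=0)
    mean_row = float(levels @ p_row)
    mean_col = float(levels @ p_col)
    var_row = float(((levels - mean_row) ** 2) @ p_row)
    var_col = float(((levels - mean_col) ** 2) @ p_col)
    return MarginalStats(mean_row, mean_col, var_row, var_col)


def texture_features(P: CooccurrenceMatrix) -> TextureFeatureVector:
    """Compute the 14 texture statistics from a normalized matrix.

    When either marginal variance is zero (single-valued image) the
    correlation is undefined; it is reported as 0 with a logged warning.
    """
    p = P.probs
    G = P.levels
    ms = marginal_stats(P)
    a, b = np.indices((G, G), dtype=np.float64)

    autocorrelation = float((a * b * p).sum())
    contrast = float((((a - b) ** 2) * p).sum())
    dissimilarity = float((np.abs(a - b) * p).sum())
    energy = float((p**2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    homogeneity = float((p / (1.0 + (a - b) ** 2)).sum())
    maximum_probability = float(p.max())

    if ms.var_row > 0 and ms.var_col > 0:
        correlation = (autocorrelation - ms.mean_row * ms.mean_col) / np.sqrt(
            ms.var_row * ms.var_col
        )
        correlation = float(correlation)
    else:
        log.warning("degenerate marginals (zero variance); reporting correlation = 0")
        correlation = 0.0

    mean = ms.mean_row
    variance = float((((a - ms.mean_row) ** 2) * p).sum())

    k_sum = np.arange(2 * G - 1, dtype=np.float64)
    p_sum = np.bincount((a + b).astype(np.int64).ravel(), weights=p.ravel(), minlength=2 * G - 1)
    sum_average = float(k_sum @ p_sum)
    sum_variance = float(((k_sum - sum_average) ** 2) @ p_sum)
    nzs = p_sum[p_sum > 0]
    sum_entropy = float(-(nzs * np.log(nzs)).sum())

    p_diff = np.bincount(np.abs(a - b).astype(np.int64).ravel(), weights=p.ravel(), minlength=G)
    nzd = p_diff[p_diff > 0]
    difference_entropy = float(-(nzd * np.log(nzd)).sum())

    return TextureFeatureVector(
        autocorrelation=autocorrelation,
        contrast=contrast,
        correlation=correlation,
        dissimilarity=dissimilarity,
        energy=energy,
        entropy=entropy,
        homogeneity=homogeneity,
        maximum_probability=maximum_probability,
        mean=mean,
        variance=variance,
        sum_average=sum_average,
        sum_variance=sum_variance,
        sum_entropy=sum_entropy,
        difference_entropy=difference_entropy,
    )


def extract(
    image: GreyImage,
    distance: int = 1,
    levels: int = 8,
    symmetric: bool = True,
    which: str = "all",
) -> dict[int | str, TextureFeatureVector]:
    """Quantize, build the five matrices and return their feature vectors.

    ``which`` selects ``"per-orientation"`` (4 vectors), ``"averaged"``
    (the single fifth-matrix vector) or ``"all"`` (5 vectors).  Keys are the
    angle in degrees or ``"avg"``.
    """
    if which not in ("per-orientation", "averaged", "all"):
        raise DataError(f"unknown selection {which!r}")
    q = quantize(image, levels) if image.levels != levels else image
    mats = cooccurrence_stack(q, distance=distance, symmetric=symmetric)
    if which == "per-orientation":
        keys: tuple[int | str, ...] = ANGLES
    elif which == "averaged":
        keys = ("avg",)
    else:
        keys = (*ANGLES, "avg")
    return {k: texture_features(mats[k]) for k in keys}
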