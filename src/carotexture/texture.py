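"""Grayscale texture features of an arterial-wall region of interest.

The five features quantify the echotexture of a normalized B-mode
ultrasound image inside an intima–media ROI mask:

* **GSM** — grayscale median of the masked pixels (echogenicity).
* **entropy** — Shannon entropy of the first-order gray-level histogram.
* **GLDM-CON** — contrast, the second moment of the gray-level
  difference histogram (gray-level difference statistics).
* **SGLD-ASM** — angular second moment of the gray-level co-occurrence
  (spatial gray-level dependence) matrix; high for uniform texture.
* **SGLD-HOM** — inverse difference moment homogeneity of the same
  matrix; high when neighbouring pixels share similar gray levels.

Pairs are accumulated at a fixed pixel displacement over the four
principal directions (0°, 45°, 90°, 135°) and only when *both* endpoints
lie inside the (possibly irregular) ROI mask; no padding is applied.
No gray-level re-quantization is performed by default (256 levels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import EmptyMaskError, NoPairsError

__all__ = [
    "ANGLE_OFFSETS",
    "TextureParams",
    "CooccurrenceMatrix",
    "DifferenceHistogram",
    "TextureFeatureSet",
    "grayscale_median",
    "histogram_entropy",
    "cooccurrence_matrix",
    "cooccurrence_entropy",
    "sgld_asm",
    "sgld_hom",
    "difference_histogram",
    "gldm_contrast",
    "extract_feature_set",
]

#: (row, col) unit offsets for the four principal directions, in degrees.
ANGLE_OFFSETS: Mapping[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}


@dataclass(frozen=True)
class TextureParams:
    """Extraction parameters attached to every feature set.

    Attributes
    ----------
    distance : int
        Displacement magnitude in pixels (default 1 px, i.e. the nearest
        neighbour at the standard 190 px/mm density).
    angles : tuple of int
        Directions (degrees) pooled into a single pair population.
    symmetric : bool
        Count each pair in both orders (the co-occurrence matrix is then
        symmetric).
    levels : int
        Number of gray levels; pixel values must lie in ``[0, levels)``.
    entropy_base : float
        Logarithm base for the entropy features.
    entropy_method : str
        ``"histogram"`` (first-order, default) or ``"cooccurrence"``.
    """

    distance: int = 1
    angles: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = True
    levels: int = 256
    entropy_base: float = 2.0
    entropy_method: str = "histogram"

    def __post_init__(self):
        if self.distance < 1:
            raise ValueError("distance must be >= 1 px")
        for a in self.angles:
            if a not in ANGLE_OFFSETS:
                raise ValueError(f"unsupported direction {a}; use 0/45/90/135")
        if self.entropy_method not in ("histogram", "cooccurrence"):
            raise ValueError("entropy_method must be 'histogram' or 'cooccurrence'")


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Joint gray-level pair probabilities at the given displacements."""

    p: np.ndarray
    displacements: tuple[tuple[int, int], ...]
    symmetric: bool
    n_pairs: int


@dataclass(frozen=True)
class DifferenceHistogram:
    """Probabilities of absolute gray-level differences ``k``."""

    p_d: np.ndarray
    displacements: tuple[tuple[int, int], ...]
    n_pairs: int


@dataclass(frozen=True)
class TextureFeatureSet:
    """The five texture scalars plus provenance."""

    gsm: float
    entropy: float
    gldm_con: float
    sgld_asm: float
    sgld_hom: float
    roi_px: int
    params: TextureParams = field(default_factory=TextureParams)

    def as_dict(self) -> dict:
        return {
            "gsm": self.gsm,
            "entropy": self.entropy,
            "gldm_con": self.gldm_con,
            "sgld_asm": self.sgld_asm,
            "sgld_hom": self.sgld_hom,
            "roi_px": self.roi_px,
        }


def _masked_values(image, mask) -> np.ndarray:
    image = np.asarray(image)
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    values = image[mask]
    if values.size == 0:
        raise EmptyMaskError("ROI mask selects no pixels")
    return values


def grayscale_median(image, mask=None) -> float:
    """Median intensity over the mask (GSM).

    With an even pixel count the mean of the two central order statistics
    is returned, so half-integer values such as 57.5 are possible.
    """
    return float(np.median(_masked_values(image, mask)))


def histogram_entropy(image, mask=None, base: float = 2.0, levels: int = 256) -> float:
    """First-order Shannon entropy of the masked gray-level histogram.

    ``-sum f(g) log f(g)`` over the ``levels``-bin relative-frequency
    histogram, with ``0 log 0 := 0``.
    """
    values = _masked_values(image, mask).astype(np.int64)
    counts = np.bincount(values.ravel(), minlength=levels)
    f = counts[counts > 0] / counts.sum()
    return float(-np.sum(f * np.log(f)) / np.log(base))


def _displacements(distance: int, angles: Sequence[int]) -> tuple[tuple[int, int], ...]:
    return tuple((ANGLE_OFFSETS[a][0] * distance, ANGLE_OFFSETS[a][1] * distance) for a in angles)


def _pair_values(image, mask, dy: int, dx: int):
    """Gray levels of all in-mask pixel pairs at offset (dy, dx)."""
    h, w = image.shape
    i0, i1 = max(0, -dy), h - max(0, dy)
    j0, j1 = max(0, -dx), w - max(0, dx)
    if i1 <= i0 or j1 <= j0:
        return None
    src = image[i0:i1, j0:j1]
    dst = image[i0 + dy:i1 + dy, j0 + dx:j1 + dx]
    valid = mask[i0:i1, j0:j1] & mask[i0 + dy:i1 + dy, j0 + dx:j1 + dx]
    if not valid.any():
        return None
    return src[valid], dst[valid]


def _prepare(image, mask, levels):
    image = np.asarray(image)
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("ROI mask selects no pixels")
    image = image.astype(np.int64)
    if image.min() < 0 or image[mask].max() >= levels:
        raise ValueError(f"pixel values must lie in [0, {levels})")
    return image, mask


def cooccurrence_matrix(
    image,
    mask=None,
    distance: int = 1,
    angles: Sequence[int] = (0, 45, 90, 135),
    symmetric: bool = True,
    levels: int = 256,
) -> CooccurrenceMatrix:
    """Spatial gray-level dependence (co-occurrence) matrix.

    Counts of ordered gray-level pairs ``(i, j)`` are accumulated over
    every displacement (one per direction, scaled by ``distance``), for
    pixel pairs whose *both* endpoints lie inside the mask, then
    normalized to a joint probability matrix.  With ``symmetric`` each
    pair is counted in both orders.
    """
    image, mask = _prepare(image, mask, levels)
    disps = _displacements(distance, angles)
    counts = np.zeros(levels * levels, dtype=np.int64)
    for dy, dx in disps:
        pairs = _pair_values(image, mask, dy, dx)
        if pairs is None:
            continue
        vi, vj = pairs
        counts += np.bincount(vi * levels + vj, minlength=levels * levels)
        if symmetric:
            counts += np.bincount(vj * levels + vi, minlength=levels * levels)
    total = int(counts.sum())
    if total == 0:
        raise NoPairsError("no valid pixel pairs inside the mask")
    p = (counts / total).reshape(levels, levels)
    return CooccurrenceMatrix(p=p, displacements=disps, symmetric=symmetric, n_pairs=total)


def difference_histogram(
    image,
    mask=None,
    distance: int = 1,
    angles: Sequence[int] = (0, 45, 90, 135),
    levels: int = 256,
) -> DifferenceHistogram:
    """Gray-level difference statistics histogram.

    Relative frequencies of ``k = |I(x) - I(x + d)|`` pooled over the
    requested directions, in-mask pairs only.
    """
    image, mask = _prepare(image, mask, levels)
    disps = _displacements(distance, angles)
    counts = np.zeros(levels, dtype=np.int64)
    for dy, dx in disps:
        pairs = _pair_values(image, mask, dy, dx)
        if pairs is None:
            continue
        vi, vj = pairs
        counts += np.bincount(np.abs(vi - vj), minlength=levels)
    total = int(counts.sum())
    if total == 0:
        raise NoPairsError("no valid pixel pairs inside the mask")
    return DifferenceHistogram(p_d=counts / total, displacements=disps, n_pairs=total)


def _p_of(P) -> np.ndarray:
    return np.asarray(getattr(P, "p", P), dtype=float)


def sgld_asm(P) -> float:
    """Angular second moment: sum of squared co-occurrence probabilities."""
    return float(np.sum(_p_of(P) ** 2))


def sgld_hom(P) -> float:
    """Inverse difference moment homogeneity: ``sum p(i,j) / (1 + (i-j)^2)``."""
    p = _p_of(P)
    n = p.shape[0]
    idx = np.arange(n)
    w = 1.0 / (1.0 + (idx[:, None] - idx[None, :]) ** 2)
    return float(np.sum(p * w))


def cooccurrence_entropy(P, base: float = 2.0) -> float:
    """Shannon entropy of the co-occurrence matrix (second-order entropy)."""
    p = _p_of(P)
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)) / np.log(base))


def gldm_contrast(D) -> float:
    """Contrast: second moment ``sum k^2 p_d(k)`` of the difference histogram."""
    p_d = np.asarray(getattr(D, "p_d", D), dtype=float)
    k = np.arange(p_d.size)
    return float(np.sum(k * k * p_d))


def extract_feature_set(image, mask=None, params: TextureParams | None = None) -> TextureFeatureSet:
    """Compute all five texture features over an ROI of a normalized image.

    Parameters
    ----------
    image : ndarray or NormalizedImage
        Normalized 8-bit image (an object with a ``pixels`` attribute is
        accepted).
    mask : ndarray of bool or RoiMask, optional
        ROI mask; an object with a ``mask`` attribute is accepted.
        ``None`` uses the whole image.
    params : TextureParams, optional
        Displacement / quantization / entropy settings.
    """
    if params is None:
        params = TextureParams()
    pixels = np.asarray(getattr(image, "pixels", image))
    roi = getattr(mask, "mask", mask)

    P = cooccurrence_matrix(
        pixels, roi, distance=params.distance, angles=params.angles,
        symmetric=params.symmetric, levels=params.levels,
    )
    D = difference_histogram(
        pixels, roi, distance=params.distance, angles=params.angles, levels=params.levels,
    )
    if params.entropy_method == "cooccurrence":
        ent = cooccurrence_entropy(P, base=params.entropy_base)
    else:
        ent = histogram_entropy(pixels, roi, base=params.entropy_base, levels=params.levels)
    roi_px = int(pixels.size if roi is None else np.count_nonzero(roi))
    return TextureFeatureSet(
        gsm=grayscale_median(pixels, roi),
        entropy=ent,
        gldm_con=gldm_contrast(D),
        sgld_asm=sgld_asm(P),
        sgld_hom=sgld_hom(P),
        roi_px=roi_px,
        params=params,
    )
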