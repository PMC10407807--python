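"""Standardized grayscale normalization and ROI geometry.

B-mode frames from different acquisitions are made comparable by a
two-point affine intensity rescale: the darkest pixel inside a blood
(lumen) reference region is mapped to 0 and the adventitia reference —
the median of the middle two intensity quartiles of a plaque-free
adventitia sample — is mapped to 190.  All analysis is done at a pixel
density of 190 px/mm; frames at another density are bilinearly resampled
first, then normalized.

ROI masks are built from two manually traced boundary polylines (the
blood–intima and media–adventitia interfaces): the mask covers the band
between the two boundaries over the distal 1.0 mm of along-wall arc
length, measured on the upper trace.  Pixel centers on the upper
boundary are included and the band is half-open on the adventitial side
so that adjacent bands never double-count a pixel row.

Coordinates are row-major, 0-based, pixel-center; traces are sequences
of ``(x, y)`` pixel positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from ._utils import as_uint8, round_half_away
from .errors import DegenerateReferenceError, EmptyMaskError, TraceError

__all__ = [
    "NormalizedImage",
    "RoiMask",
    "BLOOD_TARGET",
    "ADVENTITIA_TARGET",
    "STANDARD_DENSITY",
    "compute_reference_levels",
    "normalize_grayscale",
    "resample_to_density",
    "trace_to_roi_mask",
]

BLOOD_TARGET = 0
ADVENTITIA_TARGET = 190
#: Standard pixel density of the reading software, px per mm.
STANDARD_DENSITY = 190.0


@dataclass(frozen=True)
class NormalizedImage:
    """8-bit image on the standardized 0/190 reference scale."""

    pixels: np.ndarray
    pixel_density: float = STANDARD_DENSITY
    blood_ref: float = float(BLOOD_TARGET)
    adventitia_ref: float = float(ADVENTITIA_TARGET)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RoiMask:
    """Binary mask of the distal intima–media segment plus its trace."""

    mask: np.ndarray
    trace: np.ndarray
    length_mm: float = 1.0

    @property
    def n_pixels(self) -> int:
        return int(np.count_nonzero(self.mask))


def compute_reference_levels(
    image,
    blood_mask,
    adventitia_mask,
    adventitia_method: Literal["iqr-band", "full"] = "iqr-band",
) -> tuple[float, float]:
    """Reference intensities for the two-point normalization.

    ``blood_ref`` is the minimum intensity over the blood mask.  With the
    default ``iqr-band`` method, ``adventitia_ref`` is the median of the
    adventitia pixels whose intensity lies within the middle two
    quartiles (25th–75th percentile band) of the adventitia sample; the
    ``full`` method uses the plain median of all adventitia pixels.

    Raises
    ------
    DegenerateReferenceError
        If the adventitia reference is not strictly brighter than the
        blood reference.
    """
    image = np.asarray(image)
    blood = image[np.asarray(blood_mask, dtype=bool)]
    adv = image[np.asarray(adventitia_mask, dtype=bool)]
    if blood.size == 0 or adv.size == 0:
        raise EmptyMaskError("blood and adventitia reference masks must be non-empty")
    blood_ref = float(blood.min())
    if adventitia_method == "iqr-band":
        q25, q75 = np.percentile(adv, [25, 75])
        band = adv[(adv >= q25) & (adv <= q75)]
        adventitia_ref = float(np.median(band))
    elif adventitia_method == "full":
        adventitia_ref = float(np.median(adv))
    else:
        raise ValueError(f"unknown adventitia_method {adventitia_method!r}")
    if adventitia_ref <= blood_ref:
        raise DegenerateReferenceError(
            f"adventitia reference ({adventitia_ref}) must exceed blood reference ({blood_ref})"
        )
    return blood_ref, adventitia_ref


def normalize_grayscale(
    image,
    blood_ref: float,
    adventitia_ref: float,
    pixel_density: float = STANDARD_DENSITY,
) -> NormalizedImage:
    """Affine rescale anchoring blood to 0 and the adventitia to 190.

    ``g -> round((g - blood_ref) * 190 / (adventitia_ref - blood_ref))``,
    rounded half-away-from-zero and clipped to [0, 255].
    """
    if adventitia_ref <= blood_ref:
        raise DegenerateReferenceError("adventitia_ref must exceed blood_ref")
    pixels = np.asarray(getattr(image, "pixels", image), dtype=float)
    scale = ADVENTITIA_TARGET / (adventitia_ref - blood_ref)
    mapped = as_uint8((pixels - blood_ref) * scale)
    return NormalizedImage(
        pixels=mapped,
        pixel_density=float(pixel_density),
        blood_ref=float(blood_ref),
        adventitia_ref=float(adventitia_ref),
    )


def resample_to_density(image, pixel_density: float, target_density: float = STANDARD_DENSITY):
    """Bilinearly resample a frame to the target pixel density.

    Output size is ``round(n * target/source)`` per axis; sampling uses
    pixel-center geometry (output center ``x`` reads input coordinate
    ``(x + 0.5)/s - 0.5``) with edge clamping.  A no-op when the image is
    already at the target density.

    Returns ``(pixels, density)``.
    """
    if pixel_density is None or not pixel_density > 0:
        raise ValueError("pixel_density must be known and positive")
    pixels = np.asarray(getattr(image, "pixels", image))
    s = float(target_density) / float(pixel_density)
    if abs(s - 1.0) < 1e-12:
        return pixels, float(target_density)
    h, w = pixels.shape
    nh = max(1, int(round_half_away(h * s)))
    nw = max(1, int(round_half_away(w * s)))
    rows = (np.arange(nh) + 0.5) / s - 0.5
    cols = (np.arange(nw) + 0.5) / s - 0.5
    grid = np.meshgrid(rows, cols, indexing="ij")
    out = ndimage.map_coordinates(
        pixels.astype(float), np.stack(grid), order=1, mode="nearest"
    )
    if np.issubdtype(pixels.dtype, np.integer):
        out = as_uint8(out)
    return out, float(target_density)


def _as_trace(trace) -> np.ndarray:
    t = np.asarray(trace, dtype=float)
    if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 2:
        raise TraceError("a trace needs at least two (x, y) points")
    return t


def _interp_monotone_x(trace: np.ndarray):
    """Return (x, y, s) with x ascending and s the cumulative arc length."""
    x, y = trace[:, 0], trace[:, 1]
    seg = np.hypot(np.diff(x), np.diff(y))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if x[0] > x[-1]:  # distal end may be drawn on either side
        x, y, s = x[::-1], y[::-1], s[::-1]
    if np.any(np.diff(x) <= 0):
        raise TraceError("traces must be monotone in x (single-valued wall boundary)")
    return x, y, s


def trace_to_roi_mask(
    upper_trace,
    lower_trace,
    image_shape: tuple[int, int],
    pixel_density: float = STANDARD_DENSITY,
    length_mm: float = 1.0,
    distal: Literal["end", "start"] = "end",
) -> RoiMask:
    """Rasterize the intima–media band between two boundary traces.

    The along-wall arc length is measured on the upper (blood–intima)
    trace; the mask covers the ``length_mm`` of wall adjacent to its
    distal end.  For each pixel column in that window, rows ``r`` with
    ``y_upper <= r < y_lower`` are included (half-open on the
    adventitial side).

    Raises
    ------
    TraceError
        If the trace is shorter than ``length_mm``, the boundaries cross,
        or they come within less than one pixel of each other anywhere in
        the window.
    """
    upper = _as_trace(upper_trace)
    lower = _as_trace(lower_trace)
    h, w = image_shape
    length_px = float(length_mm) * float(pixel_density)

    ux, uy, us = _interp_monotone_x(upper)
    lx, ly, _ = _interp_monotone_x(lower)

    total = float(us[-1] - us[0])
    if total < length_px - 1e-9:
        raise TraceError(
            f"trace covers {total / pixel_density:.3f} mm; at least {length_mm} mm required"
        )

    cols = np.arange(max(0, math.ceil(ux.min())), min(w - 1, math.floor(ux.max())) + 1)
    s_cols = np.interp(cols, ux, us)
    if distal == "end":
        dist = us[-1] - s_cols
    else:
        dist = s_cols - us[0]
    keep = (dist >= 0) & (dist < length_px)
    cols = cols[keep]
    if cols.size == 0:
        raise TraceError("distal window contains no pixel columns")

    yu = np.interp(cols, ux, uy)
    yl = np.interp(cols, lx, ly)
    if np.any(yl <= yu):
        raise TraceError("boundary traces cross or touch inside the ROI window")
    if np.any(yl - yu < 1.0):
        raise TraceError("boundaries are separated by less than one pixel (empty band)")

    mask = np.zeros((h, w), dtype=bool)
    for c, a, b in zip(cols, yu, yl):
        r0 = max(0, math.ceil(a))
        r1 = min(h, math.ceil(b))
        if r1 > r0:
            mask[r0:r1, c] = True
    if not mask.any():
        raise TraceError("ROI mask is empty")
    return RoiMask(mask=mask, trace=upper, length_mm=float(length_mm))
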