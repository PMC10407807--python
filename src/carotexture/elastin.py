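"""Elastin lamella morphometry from annotated histology line profiles.

On each bright-field histology image of the arterial wall, 1–6 lines
roughly perpendicular to the vessel wall are annotated.  Each line
carries the two crossing points of the intima–media boundary and the
positions of the elastin lamellae along the line, all in micrometers.
From these the module derives, per image/side:

* intima–media thickness (mean of per-line edge spans),
* the number of elastin fibers — a weighted mean of per-line counts,
  weighted by the workable ROI length each line represents, so
  fractional values such as 4.26 are meaningful,
* summary statistics (min / max / mean / median / sample SD) of the
  distances between adjacent elastin points, pooled across the image's
  lines.

Lines flagged ``exclude`` (artifact regions) are dropped before any
computation.  All quantities are in µm; pixel-space annotations are
converted with the image's stated µm/px.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import AnnotationError

__all__ = [
    "ElastinLineAnnotation",
    "LineMetrics",
    "ElastinMetrics",
    "line_metrics",
    "weighted_fiber_count",
    "elastin_summary",
    "percent_decline",
    "read_annotation_file",
    "write_annotation_file",
]


@dataclass(frozen=True)
class ElastinLineAnnotation:
    """One annotated line profile across the intima–media layer.

    Positions (``im_edges_um``, ``elastin_um``) are distances in µm
    along the line from its first endpoint; ``p0``/``p1`` optionally
    record the endpoints in image coordinates.
    """

    line_id: int
    im_edges_um: tuple[float, float]
    elastin_um: tuple[float, ...]
    roi_segment_length_um: float = 1.0
    p0: tuple[float, float] | None = None
    p1: tuple[float, float] | None = None
    exclude: bool = False

    def validate(self) -> "ElastinLineAnnotation":
        a, b = self.im_edges_um
        if not b > a:
            raise AnnotationError(f"line {self.line_id}: IM edges must satisfy a < b")
        pts = np.asarray(self.elastin_um, dtype=float)
        if pts.size and (pts.min() < a - 1e-9 or pts.max() > b + 1e-9):
            raise AnnotationError(
                f"line {self.line_id}: elastin points must lie between the IM edges"
            )
        if pts.size > 1 and np.any(np.diff(pts) <= 0):
            raise AnnotationError(
                f"line {self.line_id}: elastin positions must be strictly increasing"
            )
        if not self.roi_segment_length_um > 0:
            raise AnnotationError(f"line {self.line_id}: ROI segment length must be > 0")
        return self


@dataclass(frozen=True)
class LineMetrics:
    """Per-line thickness, raw fiber count and adjacent spacings."""

    line_id: int
    thickness_um: float
    fiber_count: int
    distances_um: tuple[float, ...]
    roi_segment_length_um: float


@dataclass(frozen=True)
class ElastinMetrics:
    """Per-image/side elastin summary.

    Distance summaries are ``nan`` when no line contributes an adjacent
    pair; the fiber count is still reported.
    """

    imt_um: float
    n_fibers_weighted: float
    dist_min_um: float
    dist_max_um: float
    dist_mean_um: float
    dist_median_um: float
    dist_sd_um: float
    n_lines: int
    per_line: tuple[LineMetrics, ...] = field(default=(), repr=False)

    def as_dict(self) -> dict:
        return {
            "imt_um": self.imt_um,
            "n_fibers_weighted": self.n_fibers_weighted,
            "dist_min_um": self.dist_min_um,
            "dist_max_um": self.dist_max_um,
            "dist_mean_um": self.dist_mean_um,
            "dist_median_um": self.dist_median_um,
            "dist_sd_um": self.dist_sd_um,
            "n_lines": self.n_lines,
        }


def line_metrics(annotation: ElastinLineAnnotation) -> LineMetrics:
    """Thickness, fiber count and adjacent distances for one line.

    Thickness is the span between the intima–media edge points, the
    fiber count is the number of marked elastin points, and the
    distances are the successive differences of the (ordered) elastin
    positions.
    """
    a = annotation.validate()
    lo, hi = a.im_edges_um
    pts = np.asarray(a.elastin_um, dtype=float)
    distances = tuple(float(d) for d in np.diff(pts)) if pts.size > 1 else ()
    return LineMetrics(
        line_id=a.line_id,
        thickness_um=float(hi - lo),
        fiber_count=int(pts.size),
        distances_um=distances,
        roi_segment_length_um=float(a.roi_segment_length_um),
    )


def weighted_fiber_count(lines: Sequence[LineMetrics]) -> float:
    """ROI-length-weighted mean of per-line fiber counts.

    ``sum_j w_j c_j`` with ``w_j`` proportional to the along-wall ROI
    length each line represents; fractional results are expected.
    """
    if not lines:
        raise AnnotationError("at least one line is required")
    lengths = np.array([m.roi_segment_length_um for m in lines], dtype=float)
    if np.any(lengths <= 0):
        raise AnnotationError("ROI segment lengths must be positive")
    counts = np.array([m.fiber_count for m in lines], dtype=float)
    return float(np.sum(lengths * counts) / np.sum(lengths))


def elastin_summary(annotations: Sequence[ElastinLineAnnotation]) -> ElastinMetrics:
    """Pool all lines of one image/side into an :class:`ElastinMetrics`.

    Adjacent distances are pooled across lines into a single population
    before the min/max/mean/median/SD are taken (SD is the sample,
    ``n-1``, standard deviation); the intima–media thickness is the
    unweighted mean of the per-line thicknesses.
    """
    kept = [a for a in annotations if not a.exclude]
    if not kept:
        raise AnnotationError("no usable (non-excluded) lines")
    if not 1 <= len(kept) <= 6:
        raise AnnotationError("expected 1-6 usable lines per image")
    per_line = tuple(line_metrics(a) for a in kept)
    pooled = np.concatenate([np.asarray(m.distances_um, dtype=float) for m in per_line]) \
        if any(m.distances_um for m in per_line) else np.array([])
    if pooled.size:
        d_min, d_max = float(pooled.min()), float(pooled.max())
        d_mean, d_median = float(pooled.mean()), float(np.median(pooled))
        d_sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
    else:
        d_min = d_max = d_mean = d_median = d_sd = math.nan
    return ElastinMetrics(
        imt_um=float(np.mean([m.thickness_um for m in per_line])),
        n_fibers_weighted=weighted_fiber_count(per_line),
        dist_min_um=d_min,
        dist_max_um=d_max,
        dist_mean_um=d_mean,
        dist_median_um=d_median,
        dist_sd_um=d_sd,
        n_lines=len(per_line),
        per_line=per_line,
    )


def percent_decline(early: float, late: float) -> float:
    """Percent decrease from an earlier to a later group mean.

    ``100 * (early - late) / early``; negative when the value increased.
    """
    if early == 0:
        raise ValueError("early mean must be nonzero")
    return 100.0 * (early - late) / early


def read_annotation_file(path) -> list[ElastinLineAnnotation]:
    """Read a histology line-annotation JSON file.

    Expected layout::

        {"um_per_px": 0.25,
         "lines": [{"id": 1, "p0": [x, y], "p1": [x, y],
                    "im_edges_um": [a, b], "elastin_um": [...],
                    "roi_segment_length_um": L, "exclude": false}, ...]}

    Positions are in µm; ``um_per_px`` records the conversion used when
    the points were digitized.
    """
    data = json.loads(Path(path).read_text())
    out = []
    for rec in data["lines"]:
        out.append(
            ElastinLineAnnotation(
                line_id=int(rec.get("id", len(out) + 1)),
                im_edges_um=tuple(float(v) for v in rec["im_edges_um"]),
                elastin_um=tuple(float(v) for v in rec.get("elastin_um", [])),
                roi_segment_length_um=float(rec.get("roi_segment_length_um", 1.0)),
                p0=tuple(rec["p0"]) if rec.get("p0") is not None else None,
                p1=tuple(rec["p1"]) if rec.get("p1") is not None else None,
                exclude=bool(rec.get("exclude", False)),
            )
        )
    return out


def write_annotation_file(path, annotations: Sequence[ElastinLineAnnotation], um_per_px: float = 1.0):
    """Write annotations in the JSON layout of :func:`read_annotation_file`."""
    data = {
        "um_per_px": um_per_px,
        "lines": [
            {
                "id": a.line_id,
                "p0": list(a.p0) if a.p0 is not None else None,
                "p1": list(a.p1) if a.p1 is not None else None,
                "im_edges_um": list(a.im_edges_um),
                "elastin_um": list(a.elastin_um),
                "roi_segment_length_um": a.roi_segment_length_um,
                "exclude": a.exclude,
            }
            for a in annotations
        ],
    }
    Path(path).write_text(json.dumps(data, indent=1))
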