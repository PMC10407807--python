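"""Synthetic inputs with known ground truth.

Three generators make every downstream stage testable without any
external data:

* :func:`generate_wall_phantom` — a layered B-mode-like speckle phantom:
  three horizontal echogenicity bands (lumen / intima–media wall /
  adventitia) carrying multiplicative Rayleigh speckle (or additive
  Gaussian noise), with ``n_lamellae`` bright one-pixel bands embedded
  in the wall at a known spacing.  The exact band masks and lamella
  centerline rows are returned as ground truth.
* :func:`generate_line_annotations` — histology-style perpendicular
  line annotations derived from a known wall geometry, with zero-mean
  Gaussian jitter of configurable scale on the marked elastin points.
* :func:`generate_cohort` — per-animal outcome tables under a two-way
  sex-by-week cell-means model with Gaussian residuals; the default
  cell means and SDs are the reference cohort's printed group
  summaries.

No acoustics are simulated: the speckle model is the minimal one that
reproduces B-mode texture statistics (spatially correlated unit-mean
multiplicative noise on a piecewise-constant echogenicity map).  All
generators are bit-reproducible given the same spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from . import datasets
from ._utils import as_uint8, round_half_away
from .elastin import ElastinLineAnnotation
from .errors import CarotextureError, SizingError
from .normalize import STANDARD_DENSITY, NormalizedImage

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "LineGeometry",
    "CohortSpec",
    "generate_wall_phantom",
    "truth_to_geometry",
    "generate_line_annotations",
    "generate_cohort",
]


# ---------------------------------------------------------------------------
# wall phantoms


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, echogenicity and noise settings of a wall phantom.

    Intensities are on the standardized 0-255 display scale; the wall
    band occupies the middle third of the image, lumen above and
    adventitia below.  ``lamella_spacing_um`` is converted to pixels via
    ``pixel_density`` (px/mm); sub-pixel lamella positions are rounded
    half-away-from-zero.
    """

    image_height_px: int = 160
    image_width_px: int = 256
    pixel_density: float = STANDARD_DENSITY
    lumen_mean: float = 15.0
    wall_mean: float = 80.0
    adventitia_mean: float = 190.0
    n_lamellae: int = 4
    lamella_spacing_um: float = 30.0
    lamella_contrast: float = 60.0
    speckle_scale_px: float = 1.5
    noise_model: str = "multiplicative-rayleigh"
    gaussian_sd: float = 10.0
    seed: int = 0

    def validate(self) -> "PhantomSpec":
        if self.n_lamellae < 0:
            raise CarotextureError("n_lamellae must be >= 0")
        for m in (self.lumen_mean, self.wall_mean, self.adventitia_mean):
            if not 0 <= m <= 255:
                raise CarotextureError("band means must lie in [0, 255]")
        if not self.pixel_density > 0:
            raise CarotextureError("pixel_density must be positive")
        if self.noise_model not in ("multiplicative-rayleigh", "additive-gaussian"):
            raise CarotextureError(f"unknown noise model {self.noise_model!r}")
        return self

    @property
    def wall_band(self) -> tuple[int, int]:
        """Half-open row range [top, bottom) of the wall band."""
        h = self.image_height_px
        return int(round(h / 3)), int(round(2 * h / 3))


@dataclass(frozen=True)
class PhantomTruth:
    """Exact band masks and lamella centerline rows of a phantom."""

    lumen_mask: np.ndarray
    wall_mask: np.ndarray
    adventitia_mask: np.ndarray
    lamella_centerlines: tuple[int, ...]
    n_lamellae: int
    pixel_density: float = STANDARD_DENSITY


def lamella_rows(spec: PhantomSpec) -> tuple[int, ...]:
    """Integer rows of the lamella centerlines implied by a spec.

    The stack of ``n_lamellae`` lines at ``lamella_spacing_um`` is
    centered on the wall band's central row (an integer anchor, so the
    sub-pixel pattern of the rounded gaps depends only on the spacing),
    each position rounded half-away-from-zero.
    """
    n = spec.n_lamellae
    if n == 0:
        return ()
    top, bottom = spec.wall_band
    spacing_px = spec.lamella_spacing_um * spec.pixel_density / 1000.0
    anchor = (top + bottom) // 2
    offsets = (np.arange(n) - (n - 1) / 2.0) * spacing_px
    rows = round_half_away(anchor + offsets).astype(int)
    if rows.min() < top + 1 or rows.max() > bottom - 2:
        raise SizingError(
            f"{n} lamellae at {spec.lamella_spacing_um} um do not fit in the wall band "
            f"rows [{top}, {bottom})"
        )
    return tuple(int(r) for r in rows)


def generate_wall_phantom(spec: PhantomSpec) -> tuple[NormalizedImage, PhantomTruth]:
    """Render a layered speckle phantom and its ground truth.

    The echogenicity map is piecewise constant over the three bands with
    ``lamella_contrast`` added on each one-pixel lamella row.  Noise is
    multiplicative Rayleigh speckle (normalized to unit mean after
    Gaussian smoothing with ``speckle_scale_px``, so band means are
    preserved in expectation) or additive smoothed Gaussian noise.  The
    result is clipped to [0, 255] and quantized to 8 bits.
    """
    spec.validate()
    h, w = spec.image_height_px, spec.image_width_px
    top, bottom = spec.wall_band
    rows = lamella_rows(spec)

    echo = np.empty((h, w), dtype=float)
    echo[:top] = spec.lumen_mean
    echo[top:bottom] = spec.wall_mean
    echo[bottom:] = spec.adventitia_mean
    for r in rows:
        echo[r, :] += spec.lamella_contrast

    rng = np.random.default_rng(spec.seed)
    if spec.noise_model == "multiplicative-rayleigh":
        speckle = rng.rayleigh(scale=1.0, size=(h, w))
        if spec.speckle_scale_px > 0:
            speckle = ndimage.gaussian_filter(speckle, spec.speckle_scale_px)
        speckle /= speckle.mean()
        img = echo * speckle
    else:
        noise = rng.standard_normal((h, w))
        if spec.speckle_scale_px > 0:
            noise = ndimage.gaussian_filter(noise, spec.speckle_scale_px)
            sd = noise.std()
            if sd > 0:
                noise /= sd
        img = echo + spec.gaussian_sd * noise

    pixels = as_uint8(img)
    grid = np.zeros((h, w), dtype=bool)
    lumen = grid.copy(); lumen[:top] = True
    wall = grid.copy(); wall[top:bottom] = True
    adv = grid.copy(); adv[bottom:] = True
    truth = PhantomTruth(
        lumen_mask=lumen, wall_mask=wall, adventitia_mask=adv,
        lamella_centerlines=rows, n_lamellae=spec.n_lamellae,
        pixel_density=spec.pixel_density,
    )
    image = NormalizedImage(pixels=pixels, pixel_density=spec.pixel_density)
    return image, truth


# ---------------------------------------------------------------------------
# histology line annotations


@dataclass(frozen=True)
class LineGeometry:
    """Known wall cross-section: IM edges and lamella positions, in µm."""

    im_edges_um: tuple[float, float]
    lamellae_um: tuple[float, ...]

    def validate(self) -> "LineGeometry":
        a, b = self.im_edges_um
        if not b > a:
            raise CarotextureError("IM edges must satisfy a < b")
        pts = np.asarray(self.lamellae_um, float)
        if pts.size and (pts.min() < a or pts.max() > b):
            raise CarotextureError("lamellae must lie between the IM edges")
        if pts.size > 1 and np.any(np.diff(pts) <= 0):
            raise CarotextureError("lamella positions must be strictly increasing")
        return self


def truth_to_geometry(truth: PhantomTruth) -> LineGeometry:
    """Convert phantom truth to a µm cross-section along a vertical line."""
    um_per_px = 1000.0 / truth.pixel_density
    wall_rows = np.where(truth.wall_mask.any(axis=1))[0]
    top, bottom = int(wall_rows.min()), int(wall_rows.max()) + 1
    thickness = (bottom - top) * um_per_px
    lam = tuple((r - top + 0.5) * um_per_px for r in truth.lamella_centerlines)
    return LineGeometry(im_edges_um=(0.0, thickness), lamellae_um=lam)


def generate_line_annotations(
    geometry: LineGeometry | PhantomTruth,
    n_lines: int,
    jitter_um: float = 0.0,
    seed: int | None = 0,
    roi_length_um: float = 1000.0,
) -> list[ElastinLineAnnotation]:
    """Simulate 1-6 annotated perpendicular lines over a known geometry.

    Each line carries the two IM edge points and one marked point per
    ground-truth lamella, perturbed by zero-mean Gaussian jitter of
    scale ``jitter_um`` and clipped to the edge span.  The workable ROI
    length is split equally across the lines.
    """
    if not 1 <= n_lines <= 6:
        raise CarotextureError("n_lines must be between 1 and 6")
    if isinstance(geometry, PhantomTruth):
        geometry = truth_to_geometry(geometry)
    geometry.validate()
    a, b = geometry.im_edges_um
    base = np.asarray(geometry.lamellae_um, float)
    rng = np.random.default_rng(seed)
    seg = roi_length_um / n_lines
    out = []
    for j in range(n_lines):
        pts = base + (rng.normal(0.0, jitter_um, size=base.shape) if jitter_um > 0 else 0.0)
        pts = np.clip(np.sort(pts), a, b)
        if pts.size > 1 and np.any(np.diff(pts) <= 0):  # untie clipped duplicates
            pts = pts + np.arange(pts.size) * 1e-9
            pts = np.clip(pts, a, b + 1e-6)
        out.append(
            ElastinLineAnnotation(
                line_id=j + 1,
                im_edges_um=(float(a), float(b)),
                elastin_um=tuple(float(p) for p in pts),
                roi_segment_length_um=seg,
                p0=(j * seg, 0.0),
                p1=(j * seg, b - a),
            ).validate()
        )
    return out


# ---------------------------------------------------------------------------
# cohort tables


def _reference_cell_means() -> tuple[dict, dict]:
    df = datasets.texture_feature_summary()
    means: dict[str, dict[tuple[str, int], float]] = {}
    sds: dict[str, float] = {}
    for feature, g in df.groupby("feature"):
        means[feature] = {
            (r["sex"], int(r["week"])): float(r["mean"]) for _, r in g.iterrows()
        }
        sds[feature] = float(g["sd"].mean())
    return means, sds


@dataclass(frozen=True)
class CohortSpec:
    """A two-way sex-by-week simulation design.

    ``cell_means`` maps outcome name to ``{(sex, week): mean}``;
    ``residual_sd`` maps outcome name to the Gaussian residual SD.
    ``n_per_cell`` is either a single count or a per-week mapping (the
    reference cohort imaged 5/4/3 animals per sex at weeks 6/16/24).
    Defaults reproduce the reference cohort's printed group summaries.
    """

    n_per_cell: int | Mapping[int, int] = field(
        default_factory=lambda: dict(datasets.imaging_design)
    )
    weeks: tuple[int, ...] = (6, 16, 24)
    sexes: tuple[str, ...] = ("M", "F")
    cell_means: Mapping[str, Mapping[tuple[str, int], float]] | None = None
    residual_sd: Mapping[str, float] | None = None
    seed: int = 0

    def resolved(self) -> tuple[dict, dict]:
        means, sds = (self.cell_means, self.residual_sd)
        if means is None:
            ref_means, ref_sds = _reference_cell_means()
            means = ref_means
            sds = sds if sds is not None else ref_sds
        if sds is None:
            raise CarotextureError("residual_sd is required with custom cell_means")
        for outcome, cm in means.items():
            for sex in self.sexes:
                for week in self.weeks:
                    if (sex, week) not in cm:
                        raise CarotextureError(
                            f"outcome {outcome!r}: missing cell mean for ({sex}, {week})"
                        )
            if outcome not in sds or sds[outcome] < 0:
                raise CarotextureError(f"outcome {outcome!r}: residual SD must be >= 0")
        return dict(means), dict(sds)

    def cell_n(self, week: int) -> int:
        if isinstance(self.n_per_cell, Mapping):
            return int(self.n_per_cell[week])
        return int(self.n_per_cell)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a per-animal cohort table under the two-way design.

    Each record is a (sex, week) cell member with every outcome drawn as
    cell mean + Gaussian noise; reproducible from ``spec.seed``.
    """
    means, sds = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    outcomes = sorted(means)
    rows = []
    for sex in spec.sexes:
        for week in spec.weeks:
            n = spec.cell_n(week)
            for i in range(n):
                rec = {"mouse_id": f"{sex}{i + 1}", "sex": sex, "week": week}
                for outcome in outcomes:
                    mu = means[outcome][(sex, week)]
                    sd = sds[outcome]
                    rec[outcome] = mu + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                rows.append(rec)
    return pd.DataFrame(rows)
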