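# Methods

This note documents the models and procedures the package implements, the
choices made where the conventions of commercial reading software are not
public, and what the synthetic-data generators do and do not emulate.

## Grayscale normalization

Raw B-mode frames are standardized by a two-point affine intensity map

    g  ↦  round( (g − B) · 190 / (A − B) ),   clipped to [0, 255]

where `B` is the **blood reference** (the minimum intensity over a lumen
reference region) and `A` the **adventitia reference**. "Middle two-fourths
of a plaque-free adventitia segment" is ambiguous between a spatial and an
intensity selection; we read it as the *intensity* interquartile band — the
adventitia pixels whose intensity lies within the [25th, 75th] percentile
band of the adventitia sample — with `A` its median, because that choice is
independent of annotation geometry. A `full`-median alternative is exposed
(`adventitia_method`). Rounding is half-away-from-zero everywhere, for
cross-platform reproducibility.

Consequences asserted by tests: the darkest blood pixel maps to 0; the
retained adventitia band's median maps to 190 ± 1 (integer rounding); the
map is monotone; renormalizing with the image's own anchors (0, 190) is the
identity. When a frame is not at the standard 190 px/mm, it is bilinearly
resampled (pixel-center geometry, edge clamping) **before** normalization;
the opposite order is equally defensible and the resampler is exposed
separately, but the pipeline fixes resample-then-normalize.

## ROI geometry

The ROI is the intima–media band between two traced boundary polylines over
the **distal 1.0 mm of along-wall arc length**, measured on the upper
(blood–intima) trace. Conventions: row-major 0-based pixel-center
coordinates; traces single-valued in x; a pixel row `r` is in the band when
`y_upper ≤ r < y_lower` (half-open on the adventitial side so adjacent
bands never double-count); boundaries closer than 1 px anywhere in the
window, crossing boundaries, or traces shorter than 1.0 mm are errors.

## Texture features

The co-occurrence (spatial gray-level dependence) matrix accumulates
ordered gray-level pairs at displacement `d·(Δr, Δc)` for the four
principal directions (0°, 45°, 90°, 135°), both orders when symmetric,
**only when both endpoints are inside the ROI mask** (no padding), then
normalizes to probabilities. The difference histogram pools
`|I(x) − I(x+δ)|` over the same displacements. Defaults: `d = 1` px at
190 px/mm, all four directions pooled, symmetric, 256 gray levels.

The reading software's displacement, direction and quantization settings
are proprietary, so exact numeric replication of its per-image outputs is
not attempted; the defaults here are the simplest settings whose output
magnitudes are consistent with per-image values reported for this kind of
analysis (ASM of order 10⁻³ requires a fine-level matrix, hence no
re-quantization). All of these are `TextureParams` knobs.

"Entropy" is likewise not tagged with a method by the source software; both
first-order histogram entropy and co-occurrence entropy are implemented,
with first-order, log base 2, as the default (`entropy_method`,
`entropy_base`).

Cross-checks: a brute-force pair enumerator (exact count equality on random
3×3 images), `skimage.feature.graycomatrix` on rectangular masks, the
identity `CON = Σ (i−j)² p(i,j)` linking the two statistics families, and
invariance of the four-direction features under 90° rotation.

## Elastin morphometry

Each annotated line yields: thickness (span between the intima–media edge
points), a fiber count (number of marked elastin points) and adjacent
distances (successive differences), all in µm. Per image/side:

- **Weighted fiber count** `Σ w_j c_j`, `w_j ∝` the workable ROI length the
  line represents. How per-line counts combine into fractional counts is
  not standardized; the ROI-length-weighted mean is the natural reading of
  "weighted by region of interest length" and keeps the count between the
  per-line min and max.
- **Distance summaries** are computed on distances *pooled across lines*
  (one population per image), not on per-line means; per-line metrics are
  retained for transparency. SD is the sample (n−1) SD.
- **IM thickness** is the unweighted mean of per-line thicknesses (the
  per-line values are kept; whether downstream tables use per-line or mean
  thickness is not observable from published summaries).
- Lines flagged `exclude` (artifact regions) are dropped first; an image
  with fibers but no adjacent pair reports the count and NaN summaries.

## Plaque score

One point per segment with plaque (CCA, bulb, ICA, ECA), per side (0–4);
bilateral score is the sum (0–8). Downstream correlations join the per-side
score to same-side measurements, since the texture/elastin analyses use
both sides' measurements as separate records.

## Statistics

- **ANOVA**: fixed-effects cell-means model `y ~ sex * week` with sum-coded
  factors and partial (Type III) sums of squares via statsmodels OLS +
  `anova_lm(typ=3)`. Single-level factors and interactions with empty cells
  are dropped and flagged `inestimable` rather than failing the whole
  table. A term with zero SS is reported as F = 0, p = 1 even when the
  residual MS is itself zero (noise-free degenerate designs). Longitudinal
  correlation from re-imaging the same animals is deliberately ignored —
  the replicated analysis is a fixed-effects one; this is a fidelity
  choice, not a statistical endorsement.
- **Contrasts**: within-sex between-week comparisons are cell-mean
  differences with SE from the pooled within-cell mean square
  (`SE = √(MSE(1/n_a + 1/n_b))`), two-sided t on the residual df. The
  pooled MSE is computed directly from cell summaries, which a test
  verifies equals the saturated-model residual MS.
- **Spearman**: scipy's mid-rank implementation per sex, pairwise-complete
  deletion of missing values (matching the cohort's occasional missing
  side). Constant vectors are flagged undefined.
- **ICC**: the ICC variant behind published reproducibility numbers is
  rarely stated; we use ICC(A,1) — two-way random effects, absolute
  agreement, single measurement — from the subjects×readings mean squares,
  with the Satterthwaite/F-bound 95% CI (verified against pingouin).
  Printed ICCs from other software are therefore comparison points, not
  bit-reproduction targets.
- **Within-subject SD** `s_w = √(Σ d_i²/2n)`; mean and SD of `|d_i|` are
  reported alongside per-time means (SDs).
- Two-sided p-values, α = 0.05, no multiplicity adjustment — matching the
  analysis being replicated.

The null calibration of the interaction test uses a vectorized
balanced-design closed form of the two-way F statistic (500–2000
replicates at n = 1000/cell); a test first verifies the closed form agrees
with `two_way_anova` to 1e-9 on individual draws, so the calibration
exercises the same statistic.

## Synthetic data

**Phantoms** are three horizontal echogenicity bands (lumen / wall /
adventitia; defaults 15 / 80 / 190 on the standardized scale) with
`n_lamellae` one-pixel bright rows of amplitude `lamella_contrast` centered
in the wall, spaced `lamella_spacing_um` apart (sub-pixel positions rounded
half-away-from-zero, so exact truth rows exist). Speckle is multiplicative
Rayleigh noise, Gaussian-smoothed to correlation length `speckle_scale_px`
and renormalized to unit mean so band means are preserved in expectation;
an additive-Gaussian model is available. Log compression is deliberately
omitted: it would shift band means away from their specified display-scale
values, and the unit-mean multiplicative field already reproduces the
relevant second-order texture statistics. No acoustics (PSF, attenuation,
gating) are simulated, and no quantitative speckle statistics of real
acquisitions were available to calibrate against — phantom parameters are
free, documented choices. Passing phantom tests therefore demonstrates
correctness of the measurement chain and the *direction* of texture
responses (CON rises, HOM falls with lamella contrast), not performance on
real B-mode data.

**Line annotations** perturb true lamella positions with zero-mean Gaussian
jitter (clipped to the edge span), split the workable ROI length equally
across 1–6 lines, and are exactly recoverable at zero jitter.

**Cohorts** draw each outcome as cell mean + Gaussian residual under the
two-way design. Defaults are the reference cohort's printed group summaries
(per sex×week means; residual SD = the mean of the printed cell SDs) with
the study's cell sizes (5/4/3 animals per sex at weeks 6/16/24). Gaussian
residuals and independence across records are simplifications — real
readings are paired within animal and across weeks.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately small problem sizes chosen to
make Monte-Carlo error negligible relative to the asserted tolerances:
10⁴ 3×3 images for the pair-enumerator equivalence (exact), 20 seeds ×
3 contrast levels for the phantom trend, 250–300 seeds for jitter
unbiasedness (MC error ≈ 0.01 µm vs a 0.1 µm band), 500–2000 replicates
for test-size calibration (binomial SE ≈ 0.005–0.01 vs a 0.03 band), and
n = 500 subjects for ICC recovery (±0.02 band around σ_s²/(σ_s²+σ_e²) =
100/101). Probability normalizations are asserted to 1e-12 and cross-module
identities to 1e-9.

## Known limitations

- Manual traces and elastin point annotations are *inputs*; no automatic
  segmentation or ML pixel classification is provided.
- The texture defaults are principled but cannot be proven identical to
  proprietary reading software; per-image numeric agreement with such
  software is out of scope.
- The statistics module intentionally reproduces a fixed-effects analysis
  of correlated longitudinal data; use mixed models for new designs.
- Phantoms are geometric stand-ins, not acoustic simulations.
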