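"""Bundled reference-cohort summary values.

A published longitudinal cohort of ten atherosclerosis-prone
ApoE-deficient mice (5 male, 5 female; imaged at 6, 16 and 24 weeks of
age; 2, 2 and 6 animals euthanized at those weeks) provides the group
summary statistics and per-animal plaque scores used here as defaults
for the synthetic cohort generator, as worked-example inputs, and as
regression anchors for derived quantities.

Only printed group-level summaries are bundled — per-image data were
never deposited.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = [
    "plaque_scores",
    "elastin_fiber_means",
    "texture_feature_summary",
    "imaging_design",
]

#: Animals imaged per sex at each week of age.
imaging_design = {6: 5, 16: 4, 24: 3}

_PLAQUE_CSV = """\
mouse_id,sex,week,left_score,right_score
5,M,6,0,0
2,F,6,0,0
4,M,16,1,2
4,F,16,0,0
1,M,24,2,2
2,M,24,2,2
3,M,24,2,2
1,F,24,4,2
3,F,24,2,3
5,F,24,4,1
"""

_TEXTURE_CSV = """\
feature,sex,week,mean,sd
gsm,F,6,104.57,17.99
gsm,F,16,69.59,23.76
gsm,F,24,116.79,25.75
gsm,M,6,100.67,20.62
gsm,M,16,81.15,36.62
gsm,M,24,94.80,42.92
entropy,F,6,4.45,0.17
entropy,F,16,4.52,0.13
entropy,F,24,4.49,0.18
entropy,M,6,4.51,0.18
entropy,M,16,4.42,0.19
entropy,M,24,4.40,0.09
gldm_con,F,6,136.50,57.91
gldm_con,F,16,167.71,65.93
gldm_con,F,24,146.28,49.78
gldm_con,M,6,169.61,82.36
gldm_con,M,16,155.93,47.54
gldm_con,M,24,100.01,52.61
sgld_asm,F,6,0.0015,0.0005
sgld_asm,F,16,0.0015,0.0004
sgld_asm,F,24,0.0016,0.0006
sgld_asm,M,6,0.0015,0.0004
sgld_asm,M,16,0.0017,0.0005
sgld_asm,M,24,0.0018,0.0003
sgld_hom,F,6,0.15,0.04
sgld_hom,F,16,0.13,0.03
sgld_hom,F,24,0.14,0.03
sgld_hom,M,6,0.14,0.03
sgld_hom,M,16,0.15,0.04
sgld_hom,M,24,0.18,0.03
n_fibers,F,6,3.98,0.38
n_fibers,F,16,3.36,0.44
n_fibers,F,24,3.46,0.19
n_fibers,M,6,5.32,1.50
n_fibers,M,16,3.08,0.23
n_fibers,M,24,3.59,0.38
"""


def plaque_scores() -> pd.DataFrame:
    """Per-animal left/right plaque scores at euthanasia.

    Columns: mouse_id, sex, week, left_score, right_score (each side
    0-4; the bilateral score is their sum).
    """
    return pd.read_csv(io.StringIO(_PLAQUE_CSV))


def texture_feature_summary() -> pd.DataFrame:
    """Group means/SDs per feature, sex and week for the reference cohort.

    Includes the five grayscale texture features and the weighted elastin
    fiber count (``n_fibers``).
    """
    return pd.read_csv(io.StringIO(_TEXTURE_CSV))


def elastin_fiber_means() -> pd.DataFrame:
    """Weighted elastin fiber count means/SDs by sex and week."""
    df = texture_feature_summary()
    return df[df["feature"] == "n_fibers"].drop(columns="feature").reset_index(drop=True)
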