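"""Small numeric helpers used by several modules."""

from __future__ import annotations

import numpy as np


def round_half_away(x):
    """Round to the nearest integer, ties away from zero.

    ``np.round`` rounds half to even; image intensities and sub-pixel
    geometry here use the away-from-zero convention so that results are
    reproducible across platforms and easy to verify by hand.
    """
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def as_uint8(x) -> np.ndarray:
    """Clip to [0, 255], round half-away-from-zero and cast to uint8."""
    return np.clip(round_half_away(x), 0, 255).astype(np.uint8)
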