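"""Carotid plaque burden scoring.

Four arterial segments per side — common carotid artery (CCA), carotid
bulb, internal carotid artery (ICA) and external carotid artery (ECA) —
are each awarded one point when plaque is present, giving a 0–4 score
per side and a 0–8 bilateral score per animal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .errors import CarotextureError

__all__ = ["SEGMENTS", "SegmentFindings", "side_score", "bilateral_score", "score_table"]

#: The four scored arterial segments of one side.
SEGMENTS = ("cca", "bulb", "ica", "eca")


@dataclass(frozen=True)
class SegmentFindings:
    """Plaque presence flags for the four segments of one side."""

    side: str
    cca: bool
    bulb: bool
    ica: bool
    eca: bool

    @classmethod
    def from_mapping(cls, side: str, flags: Mapping[str, object]) -> "SegmentFindings":
        missing = [s for s in SEGMENTS if s not in flags or pd.isna(flags[s])]
        if missing:
            raise CarotextureError(f"missing segment flags: {missing}")
        return cls(side=side, **{s: bool(int(flags[s])) for s in SEGMENTS})


def side_score(findings: SegmentFindings) -> int:
    """Per-side score: one point per segment with plaque (0-4)."""
    return int(findings.cca) + int(findings.bulb) + int(findings.ica) + int(findings.eca)


def bilateral_score(left: SegmentFindings, right: SegmentFindings) -> int:
    """Bilateral score: sum of the two side scores (0-8)."""
    if left is None or right is None:
        raise CarotextureError("both sides are required for the bilateral score")
    return side_score(left) + side_score(right)


def score_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add ``side_score`` and ``bilateral_score`` columns to a findings table.

    Expects one row per (mouse_id, week, side) with 0/1 columns ``cca``,
    ``bulb``, ``ica``, ``eca``.  The bilateral score is attached to every
    row of a (mouse_id, week) pair once both sides are present, else NA.
    """
    out = df.copy()
    out["side_score"] = [
        side_score(SegmentFindings.from_mapping(str(r.get("side", "")), r))
        for _, r in out.iterrows()
    ]
    bilateral = out.groupby(["mouse_id", "week"])["side_score"].transform(
        lambda s: s.sum() if s.size == 2 else pd.NA
    )
    out["bilateral_score"] = bilateral
    return out
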