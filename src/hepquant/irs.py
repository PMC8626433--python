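"""Semiquantitative immunoreactive score (IRS) for OATP1B3 staining.

The IRS is the product of a positive-cell-percentage category (0-4) and a
membranous staining-intensity category (0-3), giving 0-12, binned into
negative (0), low (1-3), medium (4-8) and high (9-12).

Percentage categories: 0 = no positive cells; 1 = under 10%; 2 = 10-50%;
3 = over 50% up to 80%; 4 = over 80%. A fraction of exactly 0.10 falls in
category 2, and the 50%/80% boundaries close the lower category
(0.50 -> 2, 0.80 -> 3).
"""
from __future__ import annotations

from dataclasses import dataclass

from .cohort import INTENSITY_LABELS, LesionRecord, parse_intensity

__all__ = ["IrsResult", "percent_score", "intensity_score", "irs", "score_lesion", "CATEGORIES"]

CATEGORIES = ("negative", "low", "medium", "high")


@dataclass(frozen=True)
class IrsResult:
    percent_score: int
    intensity_score: int
    irs: int
    category: str


def percent_score(fraction: float) -> int:
    """Category (0-4) of the fraction of OATP1B3-positive tumor cells."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    if fraction == 0.0:
        return 0
    if fraction < 0.10:
        return 1
    if fraction <= 0.50:
        return 2
    if fraction <= 0.80:
        return 3
    return 4


def intensity_score(label: str) -> int:
    """Staining-intensity category: absent 0, weak 1, moderate 2, strong 3.

    Accepts symbol forms (``0``/``+``/``++``/``+++``) as well as words.
    """
    return INTENSITY_LABELS.index(parse_intensity(label))


def irs(pct_score: int, int_score: int) -> IrsResult:
    """Product score and its category bin."""
    if pct_score not in range(5):
        raise ValueError(f"percent score must be 0-4, got {pct_score}")
    if int_score not in range(4):
        raise ValueError(f"intensity score must be 0-3, got {int_score}")
    product = pct_score * int_score
    if product == 0:
        category = "negative"
    elif product <= 3:
        category = "low"
    elif product <= 8:
        category = "medium"
    else:
        category = "high"
    return IrsResult(pct_score, int_score, product, category)


def score_lesion(record: LesionRecord) -> IrsResult:
    """IRS of one cohort lesion from its raw pathology reads."""
    return irs(percent_score(record.pct_positive), intensity_score(record.intensity_label))
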