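"""Maternal distress scores: validation, thresholds and strata.

Four standardized self-report totals are modelled (item-level content is out
of scope): the Spielberger State and Trait Anxiety Inventories (SSAI, STAI;
20-80), the Perceived Stress Scale (PSS; 0-40) and the Edinburgh Postnatal
Depression Scale (EPDS; 0-30).  A score is *elevated* when it strictly
exceeds its published threshold: anxiety > 40, stress > 15, depression > 10.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

from .errors import ValidationError

log = logging.getLogger(__name__)

MEASURES: tuple[str, ...] = ("ssai", "stai", "pss", "epds")

#: inclusive scale bounds
SCALE_BOUNDS: dict[str, tuple[int, int]] = {
    "ssai": (20, 80),
    "stai": (20, 80),
    "pss": (0, 40),
    "epds": (0, 30),
}

#: strict greater-than elevation cutoffs
DEFAULT_THRESHOLDS: dict[str, int] = {"ssai": 40, "stai": 40, "pss": 15, "epds": 10}


@dataclass(frozen=True)
class DistressScores:
    """One set of questionnaire totals; ``None`` marks a missing measure."""

    ssai: int | None = None
    stai: int | None = None
    pss: int | None = None
    epds: int | None = None

    def as_dict(self) -> dict[str, int | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def validate_scores(scores: DistressScores) -> DistressScores:
    """Pass through in-range scores; missing values propagate as missing.

    Raises
    ------
    ValidationError
        Naming the offending scale if any value is outside its bounds.
    """
    for measure, value in scores.as_dict().items():
        if _is_missing(value):
            continue
        lo, hi = SCALE_BOUNDS[measure]
        if not lo <= value <= hi:
            raise ValidationError(
                f"{measure.upper()} score {value} outside its range [{lo}, {hi}]"
            )
    return scores


def classify(
    measure: str, value: float, thresholds: dict[str, int] | None = None
) -> str:
    """``"high"`` iff ``value`` strictly exceeds the measure's threshold."""
    th = DEFAULT_THRESHOLDS if thresholds is None else thresholds
    if measure not in th:
        raise ValidationError(f"unknown distress measure {measure!r}")
    lo, hi = SCALE_BOUNDS.get(measure, (-math.inf, math.inf))
    if not lo <= value <= hi:
        raise ValidationError(
            f"{measure.upper()} score {value} outside its range [{lo}, {hi}]"
        )
    return "high" if value > th[measure] else "low"


def any_elevated(
    scores: DistressScores, thresholds: dict[str, int] | None = None
) -> bool:
    """True iff at least one measure classifies high.

    Missing measures are treated as non-elevated (logged at debug level).
    """
    validate_scores(scores)
    elevated = False
    for measure, value in scores.as_dict().items():
        if _is_missing(value):
            log.debug("measure %s missing; treated as non-elevated", measure)
            continue
        if classify(measure, value, thresholds) == "high":
            elevated = True
    return elevated
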