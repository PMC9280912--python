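"""The weighted CEUS diagnostic schedule.

Four CEUS features are malignancy risk factors and carry integer weights
derived from their multivariable odds ratios: hypo-enhancement (weight 2,
the dominant factor), later arrival time, heterogeneous enhancement and
centripetal enhancement (weight 1 each).  Washout is representable in the
data model but carries no weight: it fell out of the multivariable model.

Two findings override the score as stand-alone benign indicators, in this
precedence order:

1. *absent enhancement* — the nodule takes up no contrast, the score is
   undefined and the nodule is called benign;
2. *peripheral hyper-enhancement ring* — called benign regardless of the
   numeric score.

Otherwise the nodule is called malignant iff its score reaches the cutoff
(default ≥ 2, the ROC-derived operating point).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from ceus_tirads.cohort_model import (
    Arrival,
    CEUSFeatureSet,
    EnhancementDegree,
    Homogeneity,
    Pathology,
    Pattern,
)


class AbsentEnhancementError(ValueError):
    """Raised when a numeric score is requested for a non-enhancing nodule."""


class OverrideReason(enum.Enum):
    NONE = "none"
    ABSENT_ENHANCEMENT = "absent_enhancement"
    PERIPHERAL_RING = "peripheral_ring"


@dataclass(frozen=True)
class WeightTable:
    """Nonnegative integer weights of the four CEUS risk features."""

    hypo_enhancement: int = 2
    later_arrival: int = 1
    heterogeneous: int = 1
    centripetal: int = 1

    def __post_init__(self) -> None:
        for name in ("hypo_enhancement", "later_arrival", "heterogeneous", "centripetal"):
            if getattr(self, name) < 0:
                raise ValueError(f"weight {name} must be >= 0")

    @property
    def total(self) -> int:
        return self.hypo_enhancement + self.later_arrival + self.heterogeneous + self.centripetal


DEFAULT_WEIGHTS = WeightTable()


@dataclass(frozen=True)
class Override:
    is_override: bool
    reason: OverrideReason


@dataclass(frozen=True)
class CEUSScore:
    """Weighted CEUS risk score of an enhancing nodule.

    ``value`` is the weighted feature sum (0..sum of weights; 0..5 with the
    default table).  ``overridden_benign`` marks nodules the schedule calls
    benign irrespective of the value (peripheral ring).
    """

    value: int
    overridden_benign: bool = False
    override_reason: OverrideReason = OverrideReason.NONE


def benign_override(features: CEUSFeatureSet) -> Override:
    """Stand-alone benign indicators, absent enhancement taking precedence."""
    if not features.enhancing:
        return Override(True, OverrideReason.ABSENT_ENHANCEMENT)
    if features.peripheral_ring:
        return Override(True, OverrideReason.PERIPHERAL_RING)
    return Override(False, OverrideReason.NONE)


def ceus_score(features: CEUSFeatureSet, weights: WeightTable = DEFAULT_WEIGHTS) -> CEUSScore:
    """Weighted risk score of an enhancing nodule.

    Raises
    ------
    AbsentEnhancementError
        For non-enhancing nodules, whose score is undefined; callers must
        take the :func:`benign_override` path instead.
    """
    if not features.enhancing:
        raise AbsentEnhancementError(
            "CEUS score undefined under absent enhancement; use benign_override"
        )
    value = (
        weights.hypo_enhancement * (features.enhancement_degree is EnhancementDegree.HYPO)
        + weights.later_arrival * (features.arrival is Arrival.LATER)
        + weights.heterogeneous * (features.homogeneity is Homogeneity.HETEROGENEOUS)
        + weights.centripetal * (features.pattern is Pattern.CENTRIPETAL)
    )
    override = benign_override(features)
    return CEUSScore(value=value, overridden_benign=override.is_override, override_reason=override.reason)


def ceus_call(
    features: CEUSFeatureSet,
    weights: WeightTable = DEFAULT_WEIGHTS,
    cutoff: int = 2,
) -> Pathology:
    """Dichotomous CEUS call: benign on override, else malignant iff score ≥ cutoff."""
    override = benign_override(features)
    if override.is_override:
        return Pathology.BENIGN
    return Pathology.MALIGNANT if ceus_score(features, weights).value >= cutoff else Pathology.BENIGN
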