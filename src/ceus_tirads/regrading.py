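"""The CEUS-TIRADS combination rule.

The CEUS schedule modulates the conventional-US category by at most one
level:

* absent enhancement → the nodule is re-set to category 3 outright;
* peripheral ring or score < 2 → one category down;
* score = 2 → category unchanged (deliberately conservative: a score that
  only just reaches the CEUS cutoff is not allowed to upgrade, avoiding
  CEUS false positives);
* score > 2 → one category up.

Shifts are clamped to the 2..5 scale.  The combined category dichotomizes
exactly like C-TIRADS: 4b, 4c and 5 are called malignant.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

from ceus_tirads.ceus_scoring import (
    DEFAULT_WEIGHTS,
    OverrideReason,
    WeightTable,
    benign_override,
    ceus_call,
    ceus_score,
)
from ceus_tirads.cohort_model import (
    Category,
    CEUSFeatureSet,
    Cohort,
    Pathology,
    ValidationError,
    validate_record,
)
from ceus_tirads.ctirads_grading import ctirads_call, grade


class Action(enum.Enum):
    SET_TO_3 = "set_to_3"
    DOWNGRADE = "downgrade"
    KEEP = "keep"
    UPGRADE = "upgrade"


class Trigger(enum.Enum):
    ABSENT_ENHANCEMENT = "absent_enhancement"
    RING = "ring"
    SCORE_LT_2 = "score_lt_2"
    SCORE_EQ_2 = "score_eq_2"
    SCORE_GT_2 = "score_gt_2"


@dataclass(frozen=True)
class RegradeResult:
    input_category: Category
    output_category: Category
    action: Action
    trigger: Trigger


def regrade(
    category: Category,
    features: CEUSFeatureSet,
    weights: WeightTable = DEFAULT_WEIGHTS,
) -> RegradeResult:
    """Re-grade one nodule's category according to its CEUS panel."""
    override = benign_override(features)
    if override.reason is OverrideReason.ABSENT_ENHANCEMENT:
        return RegradeResult(category, Category.C3, Action.SET_TO_3, Trigger.ABSENT_ENHANCEMENT)
    if override.reason is OverrideReason.PERIPHERAL_RING:
        return RegradeResult(category, category.shifted(-1), Action.DOWNGRADE, Trigger.RING)
    value = ceus_score(features, weights).value
    if value < 2:
        return RegradeResult(category, category.shifted(-1), Action.DOWNGRADE, Trigger.SCORE_LT_2)
    if value == 2:
        return RegradeResult(category, category, Action.KEEP, Trigger.SCORE_EQ_2)
    return RegradeResult(category, category.shifted(+1), Action.UPGRADE, Trigger.SCORE_GT_2)


def ceus_tirads_call(category: Category) -> Pathology:
    """Dichotomous CEUS-TIRADS call: 4b, 4c and 5 are malignant."""
    return Pathology.MALIGNANT if category >= Category.C4B else Pathology.BENIGN


#: Columns appended by apply_model, in output order.
ANNOTATION_COLUMNS = (
    "ctirads_category",
    "ceus_score",
    "ceus_call",
    "ceus_tirads_category",
    "ceus_tirads_call",
)


def apply_model(cohort: Cohort, weights: WeightTable = DEFAULT_WEIGHTS) -> pd.DataFrame:
    """Run the full pipeline over a cohort.

    Returns one row per record, in input order, with the record's id and
    pathology plus the five model annotations: graded (or given) C-TIRADS
    category, CEUS score (empty for non-enhancing nodules), dichotomous
    CEUS call, re-graded CEUS-TIRADS category and its dichotomous call.
    """
    bad = {rec.id: v for rec in cohort if (v := validate_record(rec))}
    if bad:
        ids = ", ".join(bad)
        raise ValidationError(f"records failing validation: {ids}")

    rows = []
    for rec in cohort:
        category = rec.ctirads_category if rec.ctirads_category is not None else grade(rec.us)
        enhancing = rec.ceus.enhancing
        score = ceus_score(rec.ceus, weights).value if enhancing else None
        result = regrade(category, rec.ceus, weights)
        rows.append(
            {
                "id": rec.id,
                "pathology": rec.pathology.value if rec.pathology else None,
                "ctirads_category": category.value,
                "ceus_score": score,
                "ceus_call": ceus_call(rec.ceus, weights).value,
                "ceus_tirads_category": result.output_category.value,
                "ceus_tirads_call": ceus_tirads_call(result.output_category).value,
                "regrade_action": result.action.value,
                "regrade_trigger": result.trigger.value,
            }
        )
    frame = pd.DataFrame(rows)
    frame["ceus_score"] = frame["ceus_score"].astype("Int64")
    return frame
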