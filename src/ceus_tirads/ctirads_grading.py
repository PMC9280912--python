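"""The C-TIRADS counting method.

Conventional-US malignancy grading by counting suspicious signs: one point
for each of *solid*, *markedly hypoechoic*, *vertical orientation*,
*microcalcifications* and *irregular or ill-defined margin* (including
extrathyroidal extension), minus one point for the benign comet-tail
artifact.  The count maps to a risk category and the category dichotomizes
at 4b: categories 4b and above are called malignant.
"""

from __future__ import annotations

from ceus_tirads.cohort_model import Category, Pathology, USFeatureSet


def us_score(features: USFeatureSet) -> int:
    """Suspicious-sign count minus the comet-tail indicator (range −1..5)."""
    positives = sum(getattr(features, name) for name in USFeatureSet.MALIGNANT_FLAGS)
    return positives - (1 if features.comet_tail else 0)


#: score → category.  Scores 1/2/3–4 are the published 4a/4b/4c rules; the
#: remaining scores follow the full C-TIRADS counting table so the mapping
#: is total: −1 and 0 fall below the biopsy band (category 3), 5 is the
#: highest count (category 5).
_SCORE_TO_CATEGORY = {
    -1: Category.C3,
    0: Category.C3,
    1: Category.C4A,
    2: Category.C4B,
    3: Category.C4C,
    4: Category.C4C,
    5: Category.C5,
}


def category_from_score(score: int) -> Category:
    """Map a US counting score to its C-TIRADS category."""
    try:
        return _SCORE_TO_CATEGORY[score]
    except KeyError:
        raise ValueError(f"US score out of range [-1, 5]: {score}") from None


def grade(features: USFeatureSet) -> Category:
    """Convenience composition ``category_from_score(us_score(features))``."""
    return category_from_score(us_score(features))


def ctirads_call(category: Category) -> Pathology:
    """Dichotomous C-TIRADS call: 4b, 4c and 5 are malignant."""
    return Pathology.MALIGNANT if category >= Category.C4B else Pathology.BENIGN
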