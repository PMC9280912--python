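# ceus-tirads

Differentiating indeterminate thyroid nodules by combining conventional
ultrasound risk stratification with a weighted contrast-enhanced ultrasound
(CEUS) score.

Nodules graded C-TIRADS 4 (sub-bands 4a/4b/4c, malignancy risk 2–90%) are
the diagnostically uncertain middle of the Chinese Thyroid Imaging Reporting
and Data System: conventional ultrasound alone calls too many of them
malignant, sending benign nodules to fine-needle aspiration. This package
implements, end to end, a **CEUS-TIRADS** model that uses the nodule's
contrast-enhancement behaviour to shift its C-TIRADS category by at most one
level, and everything needed to derive, apply and evaluate that model on
per-nodule tabular cohorts. It is written for biostatisticians and imaging
researchers who work with already-coded US/CEUS features (no image
processing is involved).

## The model

**C-TIRADS counting.** Each of five suspicious signs (solid composition,
marked hypoechogenicity, vertical orientation, microcalcifications,
irregular or ill-defined margin) adds one point; a comet-tail artifact
subtracts one. Scores map to categories (0 → 3, 1 → 4a, 2 → 4b, 3–4 → 4c,
5 → 5); categories ≥ 4b are called malignant.

**Weighted CEUS score.** Four enhancement features carry integer weights
derived from their multivariable odds ratios — hypo-enhancement **2**
(OR 39, the dominant factor), later arrival **1** (OR 24), heterogeneous
enhancement **1** (OR 6), centripetal enhancement **1** (OR 12):

```
S = 2·[hypo] + 1·[later arrival] + 1·[heterogeneous] + 1·[centripetal]   (S ∈ 0..5)
```

A nodule is CEUS-malignant iff S ≥ 2, with two stand-alone benign
overrides: absent enhancement (no contrast uptake; S is undefined) and a
regular peripheral hyper-enhancement ring. Washout is recorded but carries
no weight (it fell out of the multivariable model).

**Re-grading.** Absent enhancement re-sets the category to 3; a ring or
S < 2 moves it one band down; S = 2 keeps it (deliberately conservative);
S > 2 moves it one band up, clamped to the 2–5 scale. The combined
category dichotomizes at 4b, like C-TIRADS.

Around the model the package provides the statistics used to build it
(Pearson χ² screening, t-tests, an IRLS logistic regression, odds ratios
with Woolf intervals, the OR → weight rule), full diagnostic-performance
evaluation (sensitivity/specificity/accuracy, binary and Mann–Whitney
ordinal AUC, DeLong variance/CI and paired AUC comparison, Youden cutoff),
and two synthetic-cohort generators — a parametric class-conditional
simulator and a constraint-solving fixture builder that reconstructs a
228-nodule cohort reproducing the published study's marginal counts
(see `docs/methods.md`).

## Worked example

```python
from ceus_tirads import *

# Figure-2-style case: solid nodule with an irregular margin (C-TIRADS 4b),
# bland CEUS panel: iso-enhancement, equal arrival, homogeneous, diffuse.
from ceus_tirads.cohort_model import (Arrival, EnhancementDegree, Homogeneity,
                                      Pattern, Washout)
us = USFeatureSet(solid=True, irregular_or_illdefined_margin=True)
ceus = CEUSFeatureSet(enhancement_degree=EnhancementDegree.ISO,
                      arrival=Arrival.EQUAL_OR_EARLIER,
                      homogeneity=Homogeneity.HOMOGENEOUS,
                      pattern=Pattern.DIFFUSE,
                      washout=Washout.LATER_OR_EQUAL)
category = category_from_score(us_score(us))
result = regrade(category, ceus)
print(category.value, ceus_score(ceus).value, result.output_category.value,
      ceus_tirads_call(result.output_category).value)
```

prints

```
4b 0 4a benign
```

— two suspicious signs give C-TIRADS 4b, the CEUS score of 0 downgrades
one band to 4a, and the combined model calls the nodule benign (in the
study this case was Hashimoto's thyroiditis that conventional US alone
would have sent to biopsy).

The same pipeline over a whole cohort, from the shell:

```sh
ceus-tirads fixture study.csv            # reconstruct the study-shaped cohort
ceus-tirads regrade study.csv graded.csv # append scores, categories, calls
ceus-tirads evaluate study.csv           # Table of sens/spec/acc and AUC
```

`evaluate` on the fixture cohort reports, per grader (sens% / spec% / acc%):
C-TIRADS 93.1 / 54.5 / 74.1, CEUS 73.3 / 86.6 / 79.8, CEUS-TIRADS
95.7 / 85.7 / 90.8 — the combination repairs the specificity of
conventional US while keeping its sensitivity.

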