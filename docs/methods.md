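# Methods

This note documents the model, the statistical machinery, the synthetic
data, and the numerical and design choices the package makes where the
published description left the design open. Every number quoted here is
recomputed by the test suite or by `scripts/acceptance.py`; nothing is
asserted that the code does not itself produce.

## The diagnostic model

The pipeline operates on per-nodule records with six binary conventional-US
features, six categorical CEUS features, optional covariates (age in
years, size in millimetres, sex) and an optional histopathological label.
Malignant is the positive class throughout.

**C-TIRADS counting.** The US score is the count of the five suspicious
signs minus a comet-tail indicator, so it ranges over −1..5.
Extrathyroidal extension is folded into the irregular/ill-defined-margin
flag (the lexicon treats them as one feature). The published rule covers
scores 1–4 (4a/4b/4c); the mapping is totalized from the full counting
lexicon: −1 and 0 fall to category 3, 5 to category 5. Study-shaped
inputs only ever grade 4a–4c, so the extension never fires there.

**CEUS score and overrides.** The score is the weighted sum of four binary
risk indicators (weights 2/1/1/1 by default, configurable via
`WeightTable`). Washout is representable in the data model but carries no
weight: the package scores exactly the fitted model. Absent enhancement
makes the score *undefined* — `ceus_score` raises rather than silently
returning 0, and callers must take the override path. Override precedence
is: absent enhancement, then peripheral ring, then the score threshold.
The source description never states the ring-versus-high-score precedence
explicitly; resolving conflicts benign matches its false-negative
accounting, and the choice is empirically near-neutral (one malignant
ring-positive nodule in 116). The cutoff (default 2) and the weights are
parameters so that re-derivation experiments can vary them.

**Re-grading.** Shifts are rank arithmetic on the six-level category
scale, clamped to [2, 5]: a downgrade from 3 lands on 2, a downgrade from
2 stays 2, an upgrade from 5 stays 5. Only categories 4a–4c occur in
study-shaped cohorts, where no clamp ever fires. The score-2 "keep" rule
is implemented exactly as stated even though the CEUS dichotomy alone
calls score 2 malignant: a 4a nodule with score 2 stays 4a and is finally
called benign. This asymmetry is deliberate in the source (it avoids CEUS
false positives) and the package preserves it. Re-applying the rule to
its own output is out of contract (no idempotence is claimed).

## Model-building statistics

* **χ² tests** are Pearson without continuity correction — recomputing the
  arrival-time 2×2 (52/12 vs 64/80) reproduces the published 24.333 only
  without correction. Degenerate margins raise instead of returning NaN.
* **t-tests** come in sample-level and summary-statistic forms (the study
  publishes only means ± sd per class); pooled Student by default, Welch
  optional.
* **Logistic regression** is an own iteratively-reweighted-least-squares
  (Newton) implementation: intercept always included, convergence when the
  maximum absolute step falls below 1e−8, at most 50 iterations, standard
  errors from the inverse observed information, linear predictors clipped
  at ±30 for overflow safety. Perfect separation surfaces as a
  non-converged fit with a message, not an exception. The fit is
  cross-checked in tests against the closed-form 2×2 log odds ratio and
  against an independent reference implementation.
* **Enhancement degree** enters the multivariable model as a single binary
  hypo-vs-(iso/hyper) indicator, matching the single published OR for the
  three-level variable.
* **Weight derivation** gives the strictly largest OR weight 2 and all
  others 1; ties for largest all receive 2 and are flagged. ORs ≤ 1 are
  rejected — the schedule only counts risk-direction features.

## Diagnostic performance

Sensitivity, specificity and accuracy follow the usual definitions, with
the exact identity accuracy = prevalence·sens + (1−prevalence)·spec used
as a property test. For a single-threshold (binary) grader the ROC has
one interior vertex and the trapezoidal AUC is (sens+spec)/2 — this
exactly reproduces the published prospective-validation AUCs (0.798 for
CEUS, 0.873 for the combined model). For ordinal scores the AUC is the
Mann–Whitney pair probability with ties counted half, computed via
midranks. Variances, confidence intervals and the paired comparison of
correlated AUCs use DeLong structural components with a two-sided normal
test; both are cross-checked against an independent reference
implementation on a frozen panel. The Youden cutoff maximizes
sens+spec−1 over observed score values, breaking ties toward the lowest
threshold ("≥ threshold" is the positive call).

The normal-approximation DeLong interval is known to undercover slightly
at small samples: in the package's own calibration study (equal-variance
binormal scores, true AUC 0.7, 40 records per class, 2000 replicates)
coverage is ≈94–95%, and it drifts toward ≈92% at 20 per class or true
AUC near 0.8. This is a property of the normal approximation, not of the
variance estimator, which is unbiased in the same study.

## Synthetic cohorts

**Parametric simulator.** `default_params()` encodes the study
conditions: n=228, prevalence 116/228; per-class category mixes 7/67/41
(malignant) and 62/47/4 (benign), normalized over their printed sums; all
20 non-enhancing nodules benign (malignant absent-enhancement probability
0, benign 20/112); class-conditional enhancing-feature frequencies with
denominators 116/92 (e.g. malignant hypo-enhancement 73/116, benign ring
28/92); age 41.6±11.1 vs 46.9±12.7 years and size 9.2±5.8 vs 11.1±8.1 mm
as zero-truncated normals. US features are back-filled at random to match
the drawn category's score (3 or 4 signs equiprobably for 4c). Sex is not
simulated — the study uses it only descriptively and it is not a model
input. CEUS features are drawn **conditionally independent given class**
because only marginal frequencies are published; simulated cohorts
therefore reproduce marginal behaviour (feature frequencies, screening
power ordering, e.g. washout being the least-often-selected feature) but
*not* the published joint counts — that is precisely what the fixture
builder is for. Passing tests on simulated data accordingly validate the
machinery under the stated marginals, not the unpublished real-data
correlation structure.

**Weight-labelled simulator (recovery study).** To test that the fitting
and weight-derivation chain recovers a known generating model, a second
generator draws enhancing CEUS panels from the prevalence-pooled marginals
and assigns pathology from a logistic model whose linear predictor is the
centred weighted score, each weight unit contributing ln 6 to the log-odds
(6 being the smallest published multivariable OR). The true per-feature
OR is then exp(weight·ln 6) — 36 for hypo-enhancement, 6 for the
unit-weight features — so recovering hypo-enhancement as the dominant
factor and 2/1/1/1 from `derive_weights` is a genuine end-to-end check.
The class-conditional simulator cannot serve here: under independent
Table-2-style marginals the implied multivariable OR of centripetal
enhancement (≈45) dwarfs hypo-enhancement's (≈7), i.e. the published
multivariable ORs are not reconstructible from the published marginals.

**Fixture builder.** The published report fixes, at different
granularities: class totals (116/112); three dichotomous confusion
matrices; eleven re-grade destination counts; per-category class splits;
and several narrative cell counts. These are not perfectly mutually
consistent — the C-TIRADS confusion row sums to 115 malignant against the
116 total, and the per-category splits sum to 115/113 — so
`build_fixture` solves a small integer program over the 24 cells
(pathology × input category × action) with per-target slack variables and
lexicographic weights: class totals and the combined-model confusion are
required exactly; the C-TIRADS and CEUS-schedule confusions, destination
counts, per-category splits and narrative anchors follow in decreasing
priority, minimally relaxed in L1 and every relaxation reported. (A
weighted MILP, solved by HiGHS through SciPy, was chosen over hand-rolled
backtracking: it is deterministic, exact, and makes the priority order
explicit in the objective.) With the default constraints the solver
satisfies class totals, the combined-model confusion (111/16/5/96), the
CEUS-schedule confusion (85/15/31/97) and all eleven destination counts
exactly, at the cost of ±1 on the C-TIRADS row and on one per-category
split — the minimum possible given the source's own arithmetic.
Constraints that cannot be met even with those relaxations (e.g. more
malignant calls than nodules) raise an error naming the unsatisfiable
targets. Cells are materialized with canonical panels per trigger
(absent; score 0/1 for downgrades; score 2 for keeps; score 4 for
upgrades; one malignant ring case that exercises the ring-over-score
precedence end to end) and canonical US feature sets per category.

## Degenerate inputs and numerical conventions

Closed enumerations parse case-insensitively and reject unknown tokens
with the row and column; CSV writing is deterministic and byte-stable.
Non-enhancing records must leave the enhancement descriptors empty (the
model cannot score a partial panel; missing descriptors on enhancing
records are rejected). Records may omit pathology (prediction-only use)
and either the US features or the category — if both are present they
must agree under grading. Reported percentages round to 1 decimal, AUC
and χ² to 3, matching clinical reporting precision.

## Known limitations

* Simulated cohorts carry no inter-feature correlation beyond class
  conditioning and no reader variability.
* The fixture cohort realizes each trigger with one canonical panel, so
  its CEUS feature *marginals* (beyond the constrained counts) are not
  study-like; use the parametric simulator for marginal realism.
* Discovery-cohort AUCs published for the three dichotomized graders are
  reproducible neither by the single-threshold trapezoid nor by the
  ordinal Mann–Whitney estimator from the published counts (e.g. the
  ordinal US AUC recomputes to 0.808); the package reports its own
  estimators' values.
* The DeLong normal-approximation interval undercovers by 1–3 points at a
  few dozen records per class (see above).
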