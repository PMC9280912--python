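"""Model-building statistics.

The statistics used to derive the CEUS schedule from a labelled cohort:
Pearson χ² contingency tests (no continuity correction), two-sample
t-tests (raw samples or published summary statistics), a multivariable
logistic regression fitted by iteratively reweighted least squares, 2×2
odds ratios with Woolf intervals, and the odds-ratio → integer-weight rule
that turns the fitted model into a bedside counting score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from ceus_tirads.ceus_scoring import WeightTable
from ceus_tirads.cohort_model import (
    Arrival,
    Cohort,
    EnhancementDegree,
    Homogeneity,
    Pathology,
    Pattern,
    Washout,
)


class DegenerateTableError(ValueError):
    """A contingency table with a zero row or column margin."""


@dataclass(frozen=True)
class ContingencyTable:
    """r×c count grid, rows = feature levels, columns = pathology classes."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError(f"need an r>=2 by c>=2 table, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("negative count in contingency table")
        if counts.sum() < 1:
            raise ValueError("empty contingency table")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float
    group_means: tuple[float, float]
    group_sds: tuple[float, float]


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit (intercept first)."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    odds_ratios: np.ndarray
    converged: bool
    iterations: int
    predictor_names: tuple[str, ...] = ()
    message: str = ""


def pearson_chi2(table: ContingencyTable | np.ndarray | Sequence[Sequence[int]]) -> ChiSquareResult:
    """Pearson χ² test of independence, without continuity correction."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero row or column margin")
    stat, p, df, _ = sps.chi2_contingency(counts, correction=False)
    return ChiSquareResult(statistic=float(stat), df=int(df), p_value=float(p))


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    welch: bool = False,
) -> TTestResult:
    """Two-sided two-sample t-test (pooled Student by default, Welch optional)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs size >= 2")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0 and x.mean() == y.mean():
        raise ValueError("t undefined: both samples constant with equal means")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    df = res.df if hasattr(res, "df") else (x.size + y.size - 2 if not welch else _welch_df(x, y))
    return TTestResult(
        t=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        group_means=(float(x.mean()), float(y.mean())),
        group_sds=(float(x.std(ddof=1)), float(y.std(ddof=1))),
    )


def _welch_df(x: np.ndarray, y: np.ndarray) -> float:
    vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
    return (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))


def two_sample_t_from_stats(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    welch: bool = False,
) -> TTestResult:
    """Two-sample t-test from published summaries (mean ± sd, n) per group."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs size >= 2")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=not welch)
    if welch:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
    return TTestResult(
        t=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        group_means=(mean1, mean2),
        group_sds=(sd1, sd2),
    )


def fit_logistic(
    predictors: np.ndarray,
    outcome: Sequence[Pathology] | np.ndarray,
    predictor_names: Sequence[str] = (),
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Multivariable logistic regression by iteratively reweighted least squares.

    ``predictors`` is an (n, p) panel of binary (0/1) indicators; ``outcome``
    is a per-record pathology (malignant = 1) or a 0/1 array.  An intercept
    is always included.  Convergence is declared when the maximum absolute
    Newton step falls below ``tol``; perfect separation surfaces as a
    non-converged fit with an explanatory message rather than an exception.
    """
    X = np.column_stack([np.ones(len(predictors)), np.asarray(predictors, dtype=float)])
    y = np.asarray(
        [1.0 if o is Pathology.MALIGNANT else 0.0 for o in outcome]
        if len(outcome) and isinstance(outcome[0], Pathology)
        else outcome,
        dtype=float,
    )
    if X.shape[0] != y.shape[0]:
        raise ValueError("predictors and outcome lengths differ")
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    for j in range(1, X.shape[1]):
        if X[:, j].min() == X[:, j].max():
            raise ValueError(f"predictor {j - 1} is constant")

    beta = np.zeros(X.shape[1])
    converged = False
    message = ""
    iteration = 0
    for iteration in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        info = (X * w[:, None]).T @ X
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError("singular information matrix") from None
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if not converged:
        message = "did not converge (possible perfect separation: diverging coefficients)"
    with np.errstate(over="ignore"):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        info = (X * w[:, None]).T @ X
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            se = np.full(beta.shape, np.nan)
    return LogisticFit(
        coefficients=beta,
        standard_errors=se,
        odds_ratios=np.exp(beta),
        converged=converged,
        iterations=iteration,
        predictor_names=tuple(predictor_names),
        message=message,
    )


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci95: tuple[float, float]


def odds_ratio_2x2(
    table: ContingencyTable | np.ndarray | Sequence[Sequence[int]],
    haldane: bool = False,
) -> OddsRatioResult:
    """2×2 odds ratio ad/bc with the Woolf log-scale 95% interval.

    A zero cell makes the plain estimator degenerate; pass ``haldane=True``
    to add 0.5 to every cell (Haldane–Anscombe correction).
    """
    counts = np.asarray(table.counts if isinstance(table, ContingencyTable) else table, dtype=float)
    if counts.shape != (2, 2):
        raise ValueError(f"need a 2x2 table, got {counts.shape}")
    if haldane:
        counts = counts + 0.5
    if (counts == 0).any():
        raise ValueError("zero cell in 2x2 table; pass haldane=True for the +0.5 correction")
    a, b = counts[0]
    c, d = counts[1]
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) + np.array([-1.96, 1.96]) * se)
    return OddsRatioResult(odds_ratio=float(or_), ci95=(float(lo), float(hi)))


@dataclass(frozen=True)
class DerivedWeights:
    weights: WeightTable
    tie: bool


def derive_weights(or_by_feature: Mapping[str, float]) -> DerivedWeights:
    """Turn per-feature odds ratios into the integer counting weights.

    The feature with the strictly largest OR receives weight 2, every other
    feature weight 1; features tied for largest all receive 2 (flagged).
    Keys must be the :class:`WeightTable` field names.  Any OR ≤ 1 is
    rejected: the schedule only scores risk-direction features.
    """
    expected = {"hypo_enhancement", "later_arrival", "heterogeneous", "centripetal"}
    unknown = set(or_by_feature) - expected
    if unknown:
        raise ValueError(f"unknown feature(s): {sorted(unknown)}")
    if not or_by_feature:
        raise ValueError("no odds ratios given")
    bad = {k: v for k, v in or_by_feature.items() if v <= 1}
    if bad:
        raise ValueError(f"odds ratio(s) not in the risk direction (<= 1): {bad}")
    top = max(or_by_feature.values())
    winners = [k for k, v in or_by_feature.items() if v == top]
    weights = {k: (2 if k in winners else 1) for k in or_by_feature}
    # features absent from the map keep the schedule's unit weight
    full = {k: weights.get(k, 1) for k in expected}
    return DerivedWeights(weights=WeightTable(**full), tie=len(winners) > 1)


# ---------------------------------------------------------------------------
# Univariate screening over a cohort

@dataclass(frozen=True)
class ScreenResult:
    feature: str
    test: ChiSquareResult
    selected: bool


def _feature_table(cohort_records, feature: str) -> ContingencyTable:
    """Class-conditional level counts of one CEUS feature (enhancing nodules)."""
    levels: dict[str, type] = {
        "arrival": Arrival,
        "enhancement_degree": EnhancementDegree,
        "homogeneity": Homogeneity,
        "pattern": Pattern,
        "washout": Washout,
        "peripheral_ring": bool,
    }[feature]
    if feature == "peripheral_ring":
        row_labels = ("yes", "no")
        values = [("yes" if r.ceus.peripheral_ring else "no") for r in cohort_records]
    elif feature == "enhancement_degree":
        row_labels = ("hypo", "iso", "hyper")
        values = [r.ceus.enhancement_degree.value for r in cohort_records]
    else:
        row_labels = tuple(m.value for m in levels)
        values = [getattr(r.ceus, feature).value for r in cohort_records]
    counts = np.zeros((len(row_labels), 2), dtype=int)
    for r, v in zip(cohort_records, values):
        i = row_labels.index(v)
        j = 0 if r.pathology is Pathology.MALIGNANT else 1
        counts[i, j] += 1
    return ContingencyTable(counts=counts, row_labels=row_labels, col_labels=("malignant", "benign"))


SCREEN_FEATURES = (
    "arrival",
    "enhancement_degree",
    "homogeneity",
    "pattern",
    "washout",
    "peripheral_ring",
)


def univariate_screen(cohort: Cohort, alpha: float = 0.05) -> list[ScreenResult]:
    """χ² screen of each CEUS feature against pathology, enhancing nodules only.

    Enhancement degree enters as the 3-level hypo/iso/hyper variable, the
    others as 2-level.  A feature is selected iff p < ``alpha``.
    """
    enhancing = [r for r in cohort if r.ceus.enhancing]
    if any(r.pathology is None for r in enhancing):
        raise ValueError("univariate screen requires pathology labels on all enhancing records")
    results = []
    for feature in SCREEN_FEATURES:
        table = _feature_table(enhancing, feature)
        test = pearson_chi2(table)
        results.append(ScreenResult(feature=feature, test=test, selected=test.p_value < alpha))
    return results
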