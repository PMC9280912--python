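"""Diagnostic-performance evaluation.

Confusion-matrix metrics for dichotomous calls, single-threshold (binary)
and Mann–Whitney (ordinal) AUC estimators, DeLong variance / confidence
intervals, the paired DeLong test for correlated AUCs, and the Youden-index
operating cutoff.  Malignant is the positive class throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from ceus_tirads.cohort_model import Pathology


class UndefinedMetricError(ValueError):
    """A metric whose denominator class is empty."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("negative confusion count")
        if self.total < 1:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class PerformanceSummary:
    sensitivity: float
    specificity: float
    accuracy: float
    n: int
    auc: Optional[float] = None
    auc_ci95: Optional[tuple[float, float]] = None

    @property
    def sensitivity_pct(self) -> float:
        return round(100 * self.sensitivity, 1)

    @property
    def specificity_pct(self) -> float:
        return round(100 * self.specificity, 1)

    @property
    def accuracy_pct(self) -> float:
        return round(100 * self.accuracy, 1)


@dataclass(frozen=True)
class DeLongComparison:
    auc_a: float
    auc_b: float
    delta: float
    z: float
    p_value: float


def _truth_mask(truth: Sequence) -> np.ndarray:
    if len(truth) and isinstance(truth[0], Pathology):
        return np.array([t is Pathology.MALIGNANT for t in truth])
    return np.asarray(truth, dtype=bool)


def confusion(truth: Sequence, calls: Sequence) -> ConfusionCounts:
    """Cross-tabulate dichotomous calls against pathology (malignant positive)."""
    if len(truth) != len(calls):
        raise ValueError(f"length mismatch: {len(truth)} truths vs {len(calls)} calls")
    if not len(truth):
        raise ValueError("empty inputs")
    t = _truth_mask(truth)
    c = _truth_mask(calls)
    return ConfusionCounts(
        tp=int((t & c).sum()),
        fp=int((~t & c).sum()),
        fn=int((t & ~c).sum()),
        tn=int((~t & ~c).sum()),
    )


def metrics(conf: ConfusionCounts) -> PerformanceSummary:
    """Sensitivity, specificity and accuracy of a dichotomous call."""
    pos, neg = conf.tp + conf.fn, conf.tn + conf.fp
    if pos == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive (malignant) cases")
    if neg == 0:
        raise UndefinedMetricError("specificity undefined: no negative (benign) cases")
    return PerformanceSummary(
        sensitivity=conf.tp / pos,
        specificity=conf.tn / neg,
        accuracy=(conf.tp + conf.tn) / conf.total,
        n=conf.total,
    )


def binary_auc(conf: ConfusionCounts) -> float:
    """Trapezoidal ROC area of a single-threshold call: (sens + spec) / 2."""
    m = metrics(conf)
    return (m.sensitivity + m.specificity) / 2


def _pos_neg_scores(scores: Sequence[float], truth: Sequence) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    t = _truth_mask(truth)
    if len(s) != len(t):
        raise ValueError("length mismatch between scores and truth")
    if t.all() or not t.any():
        raise ValueError("need both classes to estimate an AUC")
    return s[t], s[~t]


def ordinal_auc(scores: Sequence[float], truth: Sequence) -> float:
    """Mann–Whitney AUC: P(score_mal > score_ben) + ½·P(equal).

    Computed with midranks, so ties count one half; equals the trapezoidal
    area under the full empirical ROC curve.
    """
    pos, neg = _pos_neg_scores(scores, truth)
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    m = len(pos)
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * len(neg)))


def _delong_components(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the DeLong structural components V10 (per positive), V01 (per negative)."""
    psi = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return float(psi.mean()), v10, v01


def delong_variance(scores: Sequence[float], truth: Sequence) -> tuple[float, float]:
    """(AUC, DeLong variance of the AUC estimator)."""
    pos, neg = _pos_neg_scores(scores, truth)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need >= 2 records per class for a DeLong variance")
    auc, v10, v01 = _delong_components(pos, neg)
    var = v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg)
    return auc, float(var)


def auc_ci(scores: Sequence[float], truth: Sequence, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """AUC with its DeLong normal-approximation confidence interval, clipped to [0, 1]."""
    auc, var = delong_variance(scores, truth)
    if var == 0:
        warnings.warn("degenerate DeLong variance (AUC 0 or 1); interval collapses", stacklevel=2)
        return auc, (auc, auc)
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return auc, (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def delong_test(scores_a: Sequence[float], scores_b: Sequence[float], truth: Sequence) -> DeLongComparison:
    """Paired DeLong z-test comparing two correlated AUCs on the same records."""
    pos_a, neg_a = _pos_neg_scores(scores_a, truth)
    pos_b, neg_b = _pos_neg_scores(scores_b, truth)
    if len(pos_a) != len(pos_b) or len(neg_a) != len(neg_b):
        raise ValueError("both predictors must score the same records")
    auc_a, v10_a, v01_a = _delong_components(pos_a, neg_a)
    auc_b, v10_b, v01_b = _delong_components(pos_b, neg_b)
    m, n = len(pos_a), len(neg_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = s10[0, 0] / m + s01[0, 0] / n + s10[1, 1] / m + s01[1, 1] / n - 2 * (s10[0, 1] / m + s01[0, 1] / n)
    delta = auc_a - auc_b
    if var <= 0:
        # identical (or perfectly concordant) predictors: no evidence of a difference
        return DeLongComparison(auc_a=auc_a, auc_b=auc_b, delta=delta, z=0.0, p_value=1.0)
    z = delta / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return DeLongComparison(auc_a=auc_a, auc_b=auc_b, delta=float(delta), z=float(z), p_value=float(p))


@dataclass(frozen=True)
class YoudenCutoff:
    threshold: float
    sensitivity: float
    specificity: float

    @property
    def j(self) -> float:
        return self.sensitivity + self.specificity - 1


def youden_cutoff(scores: Sequence[float], truth: Sequence) -> YoudenCutoff:
    """Operating threshold maximizing Youden's J = sens + spec − 1.

    A record is called positive when its score is ≥ the threshold.
    Candidates are the observed score values; ties on J break toward the
    lowest threshold.
    """
    pos, neg = _pos_neg_scores(scores, truth)
    best: Optional[YoudenCutoff] = None
    for threshold in np.unique(np.concatenate([pos, neg])):
        sens = float((pos >= threshold).mean())
        spec = float((neg < threshold).mean())
        cand = YoudenCutoff(threshold=float(threshold), sensitivity=sens, specificity=spec)
        if best is None or cand.j > best.j:
            best = cand
    assert best is not None
    return best
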