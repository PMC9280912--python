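"""Model-building statistics: χ², t-tests, logistic regression, weights."""

import numpy as np
import pytest
import statsmodels.api as sm

from ceus_tirads.ceus_scoring import WeightTable
from ceus_tirads.cohort_model import (
    Arrival,
    Category,
    CEUSFeatureSet,
    Cohort,
    EnhancementDegree,
    Homogeneity,
    NoduleRecord,
    Pathology,
    Pattern,
    Washout,
)
from ceus_tirads.feature_stats import (
    ContingencyTable,
    DegenerateTableError,
    derive_weights,
    fit_logistic,
    odds_ratio_2x2,
    pearson_chi2,
    two_sample_t,
    two_sample_t_from_stats,
    univariate_screen,
)

# class-conditional 2×2 of contrast arrival time (rows later / equal-or-earlier,
# columns malignant / benign) among the 208 enhancing study nodules
ARRIVAL_TABLE = np.array([[52, 12], [64, 80]])


def brute_force_chi2(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / counts.sum()
    return float(((counts - expected) ** 2 / expected).sum())


class TestPearsonChi2:
    def test_arrival_time_reproduces_published_statistic(self):
        res = pearson_chi2(ARRIVAL_TABLE)
        assert round(res.statistic, 3) == 24.333
        assert res.df == 1
        assert res.p_value < 0.001

    def test_agrees_with_brute_force_on_random_tables(self, rng):
        for _ in range(50):
            shape = (rng.integers(2, 5), 2)
            counts = rng.integers(1, 60, size=shape)
            res = pearson_chi2(counts)
            assert res.statistic == pytest.approx(brute_force_chi2(counts), abs=1e-10)
            assert res.df == (shape[0] - 1) * (shape[1] - 1)

    def test_proportional_rows_give_zero(self):
        assert pearson_chi2([[10, 20], [30, 60]]).statistic == pytest.approx(0.0, abs=1e-12)

    def test_peripheral_ring_table_does_not_match_misprinted_value(self):
        # the published table prints 40.796 for this 2×2; the statistic
        # recomputed from its own counts is ≈ 37.40
        res = pearson_chi2([[1, 28], [115, 64]])
        assert res.statistic == pytest.approx(brute_force_chi2([[1, 28], [115, 64]]), abs=1e-10)
        assert round(res.statistic, 2) == 37.40

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            pearson_chi2([[0, 0], [10, 20]])

    def test_permutation_invariance_and_count_scaling(self, rng):
        counts = rng.integers(1, 40, size=(3, 2))
        base = pearson_chi2(counts).statistic
        assert pearson_chi2(counts[::-1]).statistic == pytest.approx(base, abs=1e-10)
        assert pearson_chi2(counts[:, ::-1]).statistic == pytest.approx(base, abs=1e-10)
        assert pearson_chi2(counts * 3).statistic == pytest.approx(3 * base, rel=1e-12)


class TestTwoSampleT:
    def test_identical_samples(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_textbook_formula_for_shifted_sample(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([11.0, 12.0, 13.0])
        res = two_sample_t(x, y)
        sp2 = (x.var(ddof=1) + y.var(ddof=1)) / 2  # equal sizes
        expected_t = (x.mean() - y.mean()) / np.sqrt(sp2 * (2 / 3))
        assert res.t == pytest.approx(expected_t, abs=1e-12)
        assert res.df == 4

    def test_published_age_comparison_from_summaries(self):
        # 41.6±11.1 (n=116 malignant) vs 46.9±12.7 (n=112 benign)
        res = two_sample_t_from_stats(41.6, 11.1, 116, 46.9, 12.7, 112)
        assert round(res.p_value, 3) == 0.001
        assert res.df == 226

    def test_welch_equals_student_under_equal_variances_and_sizes(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30) + 0.3
        student = two_sample_t(x, y, welch=False)
        welch = two_sample_t(x, y, welch=True)
        # with equal sample sizes, the two statistics coincide exactly
        assert welch.t == pytest.approx(student.t, abs=1e-12)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0, 1.0], [1.0, 1.0])


class TestFitLogistic:
    def test_single_predictor_matches_closed_form_log_or(self):
        """A saturated one-predictor fit reproduces the 2×2 log odds ratio
        ln((52·80)/(64·12)) of the arrival-time table to 1e−6."""
        x = np.concatenate([np.ones(52), np.zeros(64), np.ones(12), np.zeros(80)])
        y = np.concatenate([np.ones(116), np.zeros(92)])
        fit = fit_logistic(x[:, None], y)
        assert fit.converged
        assert fit.coefficients[1] == pytest.approx(np.log((52 * 80) / (64 * 12)), abs=1e-6)

    def test_predictor_independent_of_outcome_gets_zero_coefficient(self):
        x = np.array([0, 1, 0, 1] * 10, dtype=float)
        y = np.array([0, 0, 1, 1] * 10, dtype=float)
        fit = fit_logistic(x[:, None], y)
        assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-8)

    def test_matches_statsmodels_on_multipredictor_panel(self, rng):
        X = (rng.random((400, 3)) < 0.4).astype(float)
        eta = -0.5 + X @ np.array([1.2, -0.7, 0.4])
        y = (rng.random(400) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert fit.converged
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.standard_errors, ref.bse, atol=1e-5)

    def test_recovers_known_log_odds_within_three_se(self, rng):
        true = np.array([np.log(39), np.log(24)])
        X = (rng.random((2000, 2)) < 0.5).astype(float)
        eta = -3.0 + X @ true
        y = (rng.random(2000) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(X, y)
        assert fit.converged
        for j in range(2):
            assert abs(fit.coefficients[j + 1] - true[j]) < 3 * fit.standard_errors[j + 1]

    def test_perfect_separation_flagged_not_raised(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = np.concatenate([np.zeros(20), np.ones(20)])
        fit = fit_logistic(x[:, None], y)
        assert not fit.converged
        assert "separation" in fit.message

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(np.ones((10, 1)), np.array([0, 1] * 5, dtype=float))

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(np.array([0.0, 1.0])[:, None], np.ones(2))


class TestOddsRatio:
    def test_arrival_time_or(self):
        res = odds_ratio_2x2(ARRIVAL_TABLE)
        assert round(res.odds_ratio, 3) == 5.417
        assert res.ci95[0] < 5.417 < res.ci95[1]

    def test_uniform_table_is_one(self):
        assert odds_ratio_2x2([[1, 1], [1, 1]]).odds_ratio == pytest.approx(1.0)

    def test_row_transposition_gives_reciprocal(self):
        fwd = odds_ratio_2x2(ARRIVAL_TABLE).odds_ratio
        rev = odds_ratio_2x2(ARRIVAL_TABLE[::-1]).odds_ratio
        assert rev == pytest.approx(1 / fwd, rel=1e-12)

    def test_zero_cell_advises_haldane(self):
        with pytest.raises(ValueError, match="haldane"):
            odds_ratio_2x2([[0, 5], [5, 5]])
        assert odds_ratio_2x2([[0, 5], [5, 5]], haldane=True).odds_ratio > 0


class TestDeriveWeights:
    def test_published_ors_give_2_1_1_1(self):
        derived = derive_weights(
            {"hypo_enhancement": 39, "later_arrival": 24, "centripetal": 12, "heterogeneous": 6}
        )
        assert derived.weights == WeightTable(2, 1, 1, 1)
        assert not derived.tie

    def test_all_tied_get_two_with_flag(self):
        derived = derive_weights(
            {"hypo_enhancement": 5, "later_arrival": 5, "centripetal": 5, "heterogeneous": 5}
        )
        assert derived.tie
        assert derived.weights == WeightTable(2, 2, 2, 2)

    def test_single_feature_is_the_largest(self):
        derived = derive_weights({"centripetal": 3.2})
        assert derived.weights.centripetal == 2

    def test_protective_or_rejected(self):
        with pytest.raises(ValueError, match="risk direction"):
            derive_weights({"hypo_enhancement": 0.8, "later_arrival": 5})


def cohort_from_marginals() -> Cohort:
    """A 208-record enhancing cohort whose per-feature class-conditional
    counts equal the published class-conditional frequencies exactly.
    (Features are assigned independently by index; each χ² screen statistic
    depends only on these marginals.)"""
    specs = {
        Pathology.MALIGNANT: dict(n=116, later=52, hypo=73, iso=26, hetero=74, centri=88, early=20, ring=1),
        Pathology.BENIGN: dict(n=92, later=12, hypo=18, iso=45, hetero=19, centri=6, early=8, ring=28),
    }
    records = []
    for path, s in specs.items():
        for i in range(s["n"]):
            if i < s["hypo"]:
                degree = EnhancementDegree.HYPO
            elif i < s["hypo"] + s["iso"]:
                degree = EnhancementDegree.ISO
            else:
                degree = EnhancementDegree.HYPER
            records.append(
                NoduleRecord(
                    id=f"{path.value}-{i}",
                    ctirads_category=Category.C4B,
                    pathology=path,
                    ceus=CEUSFeatureSet(
                        enhancement_degree=degree,
                        arrival=Arrival.LATER if i < s["later"] else Arrival.EQUAL_OR_EARLIER,
                        homogeneity=Homogeneity.HETEROGENEOUS if i < s["hetero"] else Homogeneity.HOMOGENEOUS,
                        pattern=Pattern.CENTRIPETAL if i < s["centri"] else Pattern.DIFFUSE,
                        washout=Washout.EARLIER if i < s["early"] else Washout.LATER_OR_EQUAL,
                        peripheral_ring=i < s["ring"],
                    ),
                )
            )
    return Cohort(records=records)


class TestUnivariateScreen:
    def test_screen_on_study_marginals(self):
        results = {r.feature: r for r in univariate_screen(cohort_from_marginals())}
        assert results["arrival"].selected
        assert round(results["arrival"].test.statistic, 3) == 24.333
        assert not results["washout"].selected
        assert round(results["washout"].test.statistic, 3) == 3.216
        assert results["washout"].test.p_value == pytest.approx(0.073, abs=5e-4)
        assert results["enhancement_degree"].test.df == 2
        for feature in ("enhancement_degree", "homogeneity", "pattern", "peripheral_ring"):
            assert results[feature].selected

    def test_single_class_cohort_degenerate(self):
        records = [
            NoduleRecord(
                id=f"m{i}",
                ctirads_category=Category.C4B,
                pathology=Pathology.MALIGNANT,
                ceus=CEUSFeatureSet(
                    enhancement_degree=EnhancementDegree.HYPO if i % 2 else EnhancementDegree.ISO,
                    arrival=Arrival.LATER if i % 2 else Arrival.EQUAL_OR_EARLIER,
                    homogeneity=Homogeneity.HOMOGENEOUS if i % 2 else Homogeneity.HETEROGENEOUS,
                    pattern=Pattern.DIFFUSE if i % 2 else Pattern.CENTRIPETAL,
                    washout=Washout.EARLIER if i % 2 else Washout.LATER_OR_EQUAL,
                    peripheral_ring=bool(i % 2),
                ),
            )
            for i in range(10)
        ]
        with pytest.raises(DegenerateTableError):
            univariate_screen(Cohort(records=records))
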