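"""ROC/AUC, Youden cutoff, odds ratios, logistic fit, rank tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from liquidbx.concordance import ConfusionTable, diagnostic_metrics
from liquidbx.diagnostics import (
    LabeledValues,
    auc_mann_whitney,
    crude_odds_ratio,
    detection_rates,
    dunn_posthoc,
    empirical_roc,
    fit_logistic,
    rank_tests,
    reconstruct_two_by_two,
    spearman_correlation,
    youden_cutoff,
)


def labeled(cases, controls):
    values = list(cases) + list(controls)
    labels = [True] * len(cases) + [False] * len(controls)
    return LabeledValues(values, labels)


class TestEmpiricalRoc:
    def test_perfect_separation(self):
        assert empirical_roc(labeled([2, 3, 4], [0, 1])).auc == pytest.approx(1.0)

    def test_identical_distributions(self):
        assert empirical_roc(labeled([1, 2], [1, 2])).auc == pytest.approx(0.5)

    def test_matches_pair_enumeration(self):
        cases, controls = [0.3, 0.5, 0.9], [0.2, 0.4]
        expected = auc_mann_whitney(cases, controls)  # brute-force pair count
        assert expected == pytest.approx(5 / 6)
        assert empirical_roc(labeled(cases, controls)).auc == pytest.approx(expected)

    def test_degenerate_all_equal(self):
        curve = empirical_roc(labeled([1, 1], [1, 1, 1]))
        assert curve.auc == 0.5 and curve.degenerate

    def test_ci_clipped_and_ordered(self):
        c = empirical_roc(labeled([2, 3, 4], [0, 1]))
        assert 0.0 <= c.auc_ci_low <= c.auc <= c.auc_ci_high <= 1.0

    def test_sensitivity_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        c = empirical_roc(labeled(rng.normal(1, 1, 40), rng.normal(0, 1, 40)))
        assert np.all(np.diff(c.sens_points) >= 0)  # thresholds descending

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_auc_equals_u_statistic(self, data):
        # ties made likely by rounding to one decimal
        cases = data.draw(st.lists(
            st.floats(0, 5).map(lambda x: round(x, 1)), min_size=1, max_size=15))
        controls = data.draw(st.lists(
            st.floats(0, 5).map(lambda x: round(x, 1)), min_size=1, max_size=15))
        curve = empirical_roc(labeled(cases, controls))
        assert curve.auc == pytest.approx(
            auc_mann_whitney(cases, controls), abs=1e-10)

    def test_needs_both_classes(self):
        with pytest.raises(ValueError):
            empirical_roc(labeled([1, 2], []))


class TestYoudenCutoff:
    def test_perfect_separation(self):
        data = labeled([2.0, 3.0], [0.0, 1.0])
        rep = youden_cutoff(empirical_roc(data), data)
        assert rep.youden_j == pytest.approx(1.0)
        assert rep.sensitivity == rep.specificity == 1.0
        assert 1.0 < rep.cutoff < 2.0

    def test_reference_operating_point(self):
        # 62 cases (55 above, 7 below), 30 controls (29 below, 1 above)
        data = labeled([1.0] * 55 + [0.1] * 7, [0.1] * 29 + [1.0])
        rep = youden_cutoff(empirical_roc(data), data)
        assert rep.sensitivity == pytest.approx(55 / 62)
        assert rep.specificity == pytest.approx(29 / 30)
        assert rep.youden_j == pytest.approx(55 / 62 + 29 / 30 - 1)
        assert round(rep.youden_j, 2) == 0.85
        assert rep.positive_lr == pytest.approx((55 / 62) / (1 / 30))
        assert round(rep.positive_lr, 2) == 26.61

    def test_tie_break_toward_lowest_cutoff(self):
        data = labeled([2.0, 4.0], [1.0, 3.0])
        rep = youden_cutoff(empirical_roc(data), data)
        assert rep.cutoff == pytest.approx(1.5)  # J ties at 1.5 and 3.5

    def test_self_consistent_with_metrics(self):
        rng = np.random.default_rng(7)
        data = labeled(rng.normal(1, 1, 30), rng.normal(0, 1, 25))
        rep = youden_cutoff(empirical_roc(data), data)
        m = diagnostic_metrics(rep.table)
        assert m.sensitivity == pytest.approx(rep.sensitivity)
        assert m.specificity == pytest.approx(rep.specificity)

    def test_lr_missing_at_perfect_specificity(self):
        data = labeled([5.0, 6.0, 1.0], [0.0, 0.5])
        rep = youden_cutoff(empirical_roc(data), data)
        assert rep.specificity == 1.0
        assert rep.positive_lr is None


class TestReconstruct:
    @pytest.mark.parametrize("sens,spec,nc,nn,expected", [
        (0.8871, 0.9667, 62, 30, (55, 1, 7, 29)),
        (1.0, 1.0, 10, 10, (10, 0, 0, 10)),
        (0.8226, 0.5758, 62, 33, (51, 14, 11, 19)),
    ])
    def test_examples(self, sens, spec, nc, nn, expected):
        t = reconstruct_two_by_two(sens, spec, nc, nn)
        assert (t.tp, t.fp, t.fn, t.tn) == expected

    def test_round_trip_identity_on_integer_tables(self):
        for tp, fn, tn, fp in [(55, 7, 29, 1), (3, 4, 17, 2), (1, 0, 9, 0)]:
            sens, spec = tp / (tp + fn), tn / (tn + fp)
            t = reconstruct_two_by_two(sens, spec, tp + fn, tn + fp)
            assert (t.tp, t.fp, t.fn, t.tn) == (tp, fp, fn, tn)

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_two_by_two(1.2, 1.0, 10, 10)


class TestCrudeOddsRatio:
    def test_reference_tables(self):
        r = crude_odds_ratio(ConfusionTable(55, 1, 7, 29))
        assert round(r.odds_ratio, 2) == 227.86
        assert round(r.ci_low, 2) == 26.73 and round(r.ci_high, 2) == 1942.52
        r2 = crude_odds_ratio(ConfusionTable(51, 14, 11, 19))
        assert round(r2.odds_ratio, 2) == 6.29
        assert round(r2.ci_low, 2) == 2.44 and round(r2.ci_high, 2) == 16.26

    def test_symmetric_table(self):
        assert crude_odds_ratio(ConfusionTable(5, 5, 5, 5)).odds_ratio == 1.0

    def test_haldane_correction_flagged(self):
        r = crude_odds_ratio(ConfusionTable(10, 0, 5, 20))
        assert r.haldane_corrected and r.odds_ratio is not None

    def test_degenerate_diagonal_missing(self):
        r = crude_odds_ratio(ConfusionTable(0, 5, 5, 0))
        assert r.degenerate and r.odds_ratio is None


class TestLogisticFit:
    def test_univariate_dichotomous_equals_cross_product_or(self):
        y = [1] * 55 + [1] * 7 + [0] * 1 + [0] * 29
        x = [1] * 55 + [0] * 7 + [1] * 1 + [0] * 29
        fit = fit_logistic(y, np.array(x, float), names=["exposed"])
        assert fit.converged
        assert fit.odds_ratios[1] == pytest.approx(55 * 29 / 7, rel=1e-6)

    @pytest.mark.parametrize("tp,fp,fn,tn", [(8, 3, 5, 14), (20, 10, 5, 30)])
    def test_cross_product_equivalence_property(self, tp, fp, fn, tn):
        y = [1] * (tp + fn) + [0] * (fp + tn)
        x = [1] * tp + [0] * fn + [1] * fp + [0] * tn
        fit = fit_logistic(y, np.array(x, float))
        assert fit.odds_ratios[1] == pytest.approx(tp * tn / (fp * fn), rel=1e-6)

    def test_null_predictor_not_significant(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 200)
        x = rng.normal(size=200)
        fit = fit_logistic(y, x)
        assert fit.converged
        assert abs(fit.coefficients[1]) < 0.3
        assert fit.p_values[1] > 0.05

    def test_intercept_only_balanced(self):
        y = [1] * 10 + [0] * 10
        fit = fit_logistic(y, np.empty((20, 0)))
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-8)

    def test_complete_separation_flagged(self):
        y = [0] * 10 + [1] * 10
        x = list(range(10)) + list(range(20, 30))
        fit = fit_logistic(y, np.array(x, float))
        assert fit.separation_detected and not fit.converged

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_logistic([0, 1] * 10, np.ones(20))

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        x = rng.normal(size=(80, 2))
        eta = -0.5 + x @ [1.0, -0.7]
        y = (rng.random(80) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = fit_logistic(y, x)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert fit.coefficients == pytest.approx(ref.params, abs=1e-6)
        assert fit.standard_errors == pytest.approx(ref.bse, rel=1e-4)


class TestRankTests:
    def test_mann_whitney_exact_small_sample(self):
        stat, p = rank_tests([[1, 2, 3], [4, 5, 6]], mode="mann_whitney")
        assert p == pytest.approx(0.1)  # two-sided: 2 of C(6,3)=20 orderings

    def test_identical_samples_null(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        _, p = rank_tests([x, x], mode="mann_whitney")
        assert p > 0.9

    def test_kruskal_detects_shift(self):
        g = [[1, 2, 3, 4], [5, 6, 7, 8], [9, 10, 11, 12]]
        h, p = rank_tests(g, mode="kruskal_wallis")
        assert p < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_tests([[1, 2], []], mode="mann_whitney")


class TestDunn:
    def test_constant_groups_zero_z(self):
        res = dunn_posthoc([[5, 5, 5], [5, 5, 5], [5, 5, 5]])
        assert all(r["z"] == 0.0 for r in res)

    def test_toy_fixture_matches_pooled_rank_formula(self):
        # ranks 1..6, no ties: var_core = 6*7/12 = 3.5, rank means 1.5/3.5/5.5
        res = dunn_posthoc([[1, 2], [3, 4], [5, 6]])
        z = {(r["group_i"], r["group_j"]): r["z"] for r in res}
        expected = -2.0 / math.sqrt(3.5)
        assert z[(0, 1)] == pytest.approx(expected)
        assert z[(1, 2)] == pytest.approx(expected)
        assert z[(0, 2)] == pytest.approx(2 * expected)

    def test_z_ordering_matches_separation(self):
        res = dunn_posthoc([[1, 2, 3], [10, 11, 12], [5, 6, 7]])
        z = {(r["group_i"], r["group_j"]): abs(r["z"]) for r in res}
        assert z[(0, 1)] > z[(0, 2)]  # widest separation, largest |z|

    def test_bonferroni_never_smaller(self):
        res = dunn_posthoc([[1, 2, 3], [2, 3, 4], [8, 9, 10]])
        assert all(r["p_bonferroni"] >= r["p_unadjusted"] for r in res)

    def test_needs_three_groups(self):
        with pytest.raises(ValueError):
            dunn_posthoc([[1], [2]])


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_correlation([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_fixture(self):
        # d = (1,-1,1,-1) on ranks: rho = 1 - 6*4/(4*15) = 0.6
        rho, _ = spearman_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    def test_missing_pairs_dropped(self):
        rho, _ = spearman_correlation(
            [1, 2, 3, 4, np.nan], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.6)

    def test_constant_vector_missing(self):
        rho, p = spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])
        assert rho is None and p is None


class TestDetectionRates:
    def test_reference_rates(self):
        vals = {
            "cfdna": [1.0] * 54 + [0.1] * 8,           # 54/62 above cutoff
            "ctdna_mutations": [1] * 9 + [0],          # 9/10 with >=1 mutation
        }
        rates = detection_rates(vals, {"cfdna": 0.2175, "ctdna_mutations": 1})
        assert rates["cfdna"] == pytest.approx(54 / 62)
        assert round(100 * rates["cfdna"], 2) == 87.10
        assert rates["ctdna_mutations"] == pytest.approx(0.9)

    def test_threshold_below_everything(self):
        rates = detection_rates({"m": [1.0, 2.0, 3.0]}, {"m": 0.0})
        assert rates["m"] == 1.0

    def test_missing_excluded_from_denominator(self):
        rates = detection_rates({"m": [5.0, None, 1.0, None]}, {"m": 2.0})
        assert rates["m"] == pytest.approx(0.5)

    def test_empty_evaluable_missing(self):
        rates = detection_rates({"m": [None, None]}, {"m": 1.0})
        assert rates["m"] is None
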