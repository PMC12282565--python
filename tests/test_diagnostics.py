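import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import expit

from fasila.diagnostics import (
    AUCComparison,
    BinaryConfusion,
    CIMethod,
    DegenerateDataError,
    DiagnosticsError,
    GroupTest,
    auroc_bootstrap_compare,
    auroc_mann_whitney,
    confusion_from_threshold,
    diagnostic_metrics,
    group_comparison,
    logistic_irls,
    odds_ratio,
    pearson_correlation,
    proportion_ci,
    two_proportion_power,
)

# ---------------------------------------------------------------------------
# independent oracles


def auc_pairwise_oracle(scores, outcome):
    """Brute-force double loop over all case-control pairs."""
    pos = [s for s, y in zip(scores, outcome) if y]
    neg = [s for s, y in zip(scores, outcome) if not y]
    num = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                num += 1.0
            elif p == q:
                num += 0.5
    return num / (len(pos) * len(neg))


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration over the table
    family with fixed margins: sum probabilities <= that of the observed table."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


# ---------------------------------------------------------------------------
# confusion tables and metrics


class TestConfusion:
    def test_table1_surgery_reconstruction(self, table1_scored):
        from fasila.report import outcome_vector

        y = outcome_vector(table1_scored, "surgery")
        conf = confusion_from_threshold(
            table1_scored["fasila_total"].to_numpy(float), y, 4
        )
        assert (conf.tp, conf.fp, conf.fn, conf.tn) == (33, 44, 64, 259)

    def test_all_negative_outcome(self):
        conf = confusion_from_threshold([1, 2, 3], [False] * 3, 2)
        assert conf.tp == 0 and conf.fn == 0

    def test_cutoff_above_max(self):
        conf = confusion_from_threshold([1, 2, 3], [True, False, True], 99)
        assert conf.tp == 0 and conf.fp == 0

    def test_strict_inequality(self):
        conf = confusion_from_threshold([0.8, 0.81], [True, True], 0.8, strict=True)
        assert (conf.tp, conf.fn) == (1, 1)

    def test_length_mismatch(self):
        with pytest.raises(DiagnosticsError):
            confusion_from_threshold([1, 2], [True], 1)

    def test_empty(self):
        with pytest.raises(DiagnosticsError):
            confusion_from_threshold([], [], 1)


class TestDiagnosticMetrics:
    def test_reconstructed_table(self):
        panel = diagnostic_metrics(BinaryConfusion(33, 44, 64, 259))
        assert round(100 * panel.sensitivity.estimate, 1) == 34.0
        assert round(100 * panel.specificity.estimate, 1) == 85.5
        # 33/77 = 42.857...% -> 42.9 at one decimal (printed source shows 42.8)
        assert round(100 * panel.ppv.estimate, 1) == 42.9
        assert round(100 * panel.npv.estimate, 1) == 80.2

    def test_perfect_test(self):
        panel = diagnostic_metrics(BinaryConfusion(10, 0, 0, 10))
        for p in (panel.sensitivity, panel.specificity, panel.ppv, panel.npv):
            assert p.estimate == 1.0

    def test_degenerate_ppv_undefined(self):
        panel = diagnostic_metrics(BinaryConfusion(0, 0, 5, 5))
        assert panel.sensitivity.estimate == 0.0
        assert panel.ppv is None

    def test_no_condition_positives_raises(self):
        with pytest.raises(DegenerateDataError):
            diagnostic_metrics(BinaryConfusion(0, 5, 0, 5))

    @given(
        tp=st.integers(0, 30), fp=st.integers(0, 30),
        fn=st.integers(0, 30), tn=st.integers(0, 30),
    )
    def test_metric_identities_and_ci_bracketing(self, tp, fp, fn, tn):
        if tp + fn == 0 or fp + tn == 0:
            return
        panel = diagnostic_metrics(BinaryConfusion(tp, fp, fn, tn))
        assert panel.sensitivity.estimate * (tp + fn) == pytest.approx(tp)
        for p in (panel.sensitivity, panel.specificity, panel.ppv, panel.npv):
            if p is not None:
                assert p.lo <= p.estimate <= p.hi

    def test_binary_auc_identity(self):
        panel = diagnostic_metrics(BinaryConfusion(33, 44, 64, 259))
        assert panel.auc_binary == pytest.approx(
            (panel.sensitivity.estimate + panel.specificity.estimate) / 2
        )


class TestProportionCI:
    def test_clopper_pearson_matches_beta_inversion(self):
        ci = proportion_ci(33, 97)
        assert ci.lo == pytest.approx(stats.beta.ppf(0.025, 33, 65))
        assert ci.hi == pytest.approx(stats.beta.ppf(0.975, 34, 64))

    def test_clopper_pearson_extremes(self):
        assert proportion_ci(0, 10).lo == 0.0
        assert proportion_ci(10, 10).hi == 1.0

    def test_wilson_known_value(self):
        # closed form checked by hand for k=5, n=10, z=1.959964
        ci = proportion_ci(5, 10, CIMethod.WILSON)
        assert ci.lo == pytest.approx(0.2366, abs=2e-4)
        assert ci.hi == pytest.approx(0.7634, abs=2e-4)

    def test_invalid(self):
        with pytest.raises(DiagnosticsError):
            proportion_ci(5, 0)


# ---------------------------------------------------------------------------
# ROC / AUROC


class TestAuroc:
    def test_table1_surgery_value(self, table1_scored):
        from fasila.report import outcome_vector

        y = outcome_vector(table1_scored, "surgery")
        roc = auroc_mann_whitney(table1_scored["fasila_total"].to_numpy(float), y)
        assert round(roc.auc, 2) == 0.69

    def test_perfect_separation(self):
        roc = auroc_mann_whitney([1, 1, 0, 0], [True, True, False, False])
        assert roc.auc == 1.0

    def test_all_ties(self):
        roc = auroc_mann_whitney([2, 2, 2, 2], [True, False, True, False])
        assert roc.auc == 0.5

    def test_single_class_raises(self):
        with pytest.raises(DegenerateDataError):
            auroc_mann_whitney([1, 2], [True, True])

    def test_curve_shape(self):
        roc = auroc_mann_whitney([3, 1, 2, 0], [True, False, True, False])
        assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
        assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)

    @settings(max_examples=300, deadline=None)
    @given(st.data())
    def test_equals_pairwise_oracle(self, data):
        n = data.draw(st.integers(2, 60))
        scores = data.draw(
            st.lists(st.integers(0, 6), min_size=n, max_size=n)
        )
        outcome = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda y: any(y) and not all(y)
            )
        )
        assert auroc_mann_whitney(scores, outcome).auc == pytest.approx(
            auc_pairwise_oracle(scores, outcome)
        )

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_invariant_under_monotone_transform(self, data):
        n = data.draw(st.integers(4, 40))
        scores = np.array(data.draw(st.lists(st.integers(0, 6), min_size=n, max_size=n)), float)
        outcome = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda y: any(y) and not all(y)
            )
        )
        base = auroc_mann_whitney(scores, outcome).auc
        for f in (lambda s: 3 * s + 1, lambda s: np.exp(s), lambda s: s ** 3):
            assert auroc_mann_whitney(f(scores), outcome).auc == pytest.approx(base)

    def test_binary_predictor_equals_mean_sens_spec(self, table1_scored):
        from fasila.report import outcome_vector

        y = outcome_vector(table1_scored, "surgery")
        scores = table1_scored["fasila_total"].to_numpy(float)
        binary = (scores >= 4).astype(float)
        conf = confusion_from_threshold(scores, y, 4)
        panel = diagnostic_metrics(conf)
        assert auroc_mann_whitney(binary, y).auc == pytest.approx(panel.auc_binary)


class TestBootstrapCompare:
    def test_identical_scores_zero_delta(self):
        rng = np.random.default_rng(0)
        s = rng.integers(0, 7, 80).astype(float)
        y = rng.random(80) < 0.4
        y[0], y[1] = True, False
        res = auroc_bootstrap_compare(s, s, y, n_boot=200, seed=5)
        assert res.delta == 0.0
        assert res.delta_ci == (0.0, 0.0)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=60)
        b = rng.normal(size=60)
        y = rng.random(60) < 0.5
        y[0], y[1] = True, False
        r1 = auroc_bootstrap_compare(a, b, y, n_boot=100, seed=42)
        r2 = auroc_bootstrap_compare(a, b, y, n_boot=100, seed=42)
        assert r1 == r2

    def test_informative_vs_random_excludes_zero(self):
        rng = np.random.default_rng(7)
        n = 300
        y = np.zeros(n, bool)
        y[:120] = True
        a = np.where(y, 1.0, 0.0)  # perfect
        b = rng.normal(size=n)  # uninformative
        res = auroc_bootstrap_compare(a, b, y, n_boot=500, seed=3)
        assert res.delta_ci[0] > 0

    def test_constant_comparator(self, table1_scored):
        from fasila.report import outcome_vector

        y = outcome_vector(table1_scored, "surgery")
        s = table1_scored["fasila_total"].to_numpy(float)
        res = auroc_bootstrap_compare(s, np.zeros_like(s), y, n_boot=10, seed=0)
        assert res.auc_b == 0.5
        assert res.delta == pytest.approx(res.auc_a - 0.5)


# ---------------------------------------------------------------------------
# association


class TestOddsRatio:
    def test_reconstructed_value(self):
        res = odds_ratio(BinaryConfusion(33, 44, 64, 259))
        assert res.or_estimate == pytest.approx(3.035, abs=5e-3)
        assert not res.continuity_corrected
        assert res.lo < res.or_estimate < res.hi

    @pytest.mark.parametrize("a,b", [(3, 5), (10, 10), (1, 7)])
    def test_no_association(self, a, b):
        res = odds_ratio(BinaryConfusion(a, b, a, b))
        assert res.or_estimate == pytest.approx(1.0)

    def test_zero_cell_correction(self):
        res = odds_ratio(BinaryConfusion(1, 0, 1, 1))
        assert res.continuity_corrected
        assert res.or_estimate == pytest.approx((1.5 * 1.5) / (0.5 * 1.5))

    def test_empty_margin_raises(self):
        with pytest.raises(DegenerateDataError):
            odds_ratio(BinaryConfusion(0, 0, 3, 4))


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        res = pearson_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, -x).r == pytest.approx(-1.0)

    def test_pairwise_deletion(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.1, 2.2, 3.0, np.nan, 5.2]
        res = pearson_correlation(x, y)
        assert res.n == 3

    def test_zero_variance(self):
        with pytest.raises(DegenerateDataError):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_p_value_matches_t_transform(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = pearson_correlation(x, y)
        t = res.r * math.sqrt((res.n - 2) / (1 - res.r**2))
        p = 2 * stats.t.sf(abs(t), res.n - 2)
        assert res.p_two_sided == pytest.approx(p)


class TestGroupComparison:
    def test_fisher_balanced_identical(self):
        res = group_comparison([[5, 5], [5, 5]], GroupTest.FISHER_EXACT)
        assert res.p_value == pytest.approx(1.0)

    def test_fisher_equals_enumeration(self):
        for table in [(10, 0, 0, 10), (3, 7, 6, 2), (1, 9, 8, 4), (0, 5, 5, 0)]:
            a, b, c, d = table
            res = group_comparison([[a, b], [c, d]], GroupTest.FISHER_EXACT)
            assert res.p_value == pytest.approx(
                fisher_enumeration_oracle(a, b, c, d), rel=1e-9
            )

    def test_chi_square_falls_back_to_fisher(self):
        res = group_comparison([[2, 3], [1, 4]], GroupTest.CHI_SQUARE)
        assert res.fell_back_to_fisher
        assert res.test_used is GroupTest.FISHER_EXACT

    def test_chi_square_large_table(self):
        table = [[50, 60], [40, 70]]
        res = group_comparison(table, GroupTest.CHI_SQUARE)
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        assert res.statistic == pytest.approx(chi2)
        assert not res.fell_back_to_fisher

    def test_welch_equal_means(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 500)
        b = rng.normal(0, 2, 500)
        res = group_comparison([a, b], GroupTest.WELCH_T)
        assert abs(res.statistic) < 3

    def test_anova(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 1, 30) for m in (0, 0.1, -0.1)]
        res = group_comparison(groups, GroupTest.ONE_WAY_ANOVA)
        f, p = stats.f_oneway(*groups)
        assert res.statistic == pytest.approx(f)

    def test_empty_margin(self):
        with pytest.raises(DegenerateDataError):
            group_comparison([[0, 0], [3, 4]], GroupTest.CHI_SQUARE)


# ---------------------------------------------------------------------------
# logistic regression


class TestLogisticIrls:
    def test_intercept_only_structure(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=500)
        y = rng.random(500) < 0.3  # independent of x
        fit = logistic_irls(x[:, None], y.astype(float))
        assert fit.converged
        assert fit.odds_ratios[1] == pytest.approx(1.0, abs=0.3)
        assert fit.coef[0] == pytest.approx(
            math.log(y.mean() / (1 - y.mean())), abs=0.3
        )

    def test_parameter_recovery(self):
        rng = np.random.default_rng(6)
        n = 2000
        x = rng.normal(size=n)
        beta = (-2.0, 0.65)
        y = rng.random(n) < expit(beta[0] + beta[1] * x)
        fit = logistic_irls(x[:, None], y.astype(float))
        assert fit.converged
        for j in range(2):
            assert abs(fit.coef[j] - beta[j]) < 3 * fit.se[j]

    def test_matches_two_by_two_odds_ratio(self):
        # binary predictor: Wald OR equals the contingency-table OR
        tp, fp, fn, tn = 20, 15, 10, 40
        x = np.array([1.0] * (tp + fp) + [0.0] * (fn + tn))
        y = np.array([1.0] * tp + [0.0] * fp + [1.0] * fn + [0.0] * tn)
        fit = logistic_irls(x[:, None], y)
        table_or = odds_ratio(BinaryConfusion(tp, fp, fn, tn))
        assert fit.odds_ratios[1] == pytest.approx(table_or.or_estimate, rel=1e-6)
        ci = fit.or_ci()[1]
        assert ci[0] == pytest.approx(table_or.lo, rel=1e-6)
        assert ci[1] == pytest.approx(table_or.hi, rel=1e-6)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(8)
        n = 400
        X = rng.normal(size=(n, 2))
        y = (rng.random(n) < expit(-0.5 + 0.8 * X[:, 0] - 0.4 * X[:, 1])).astype(float)
        fit = logistic_irls(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert fit.coef == pytest.approx(ref.params, abs=1e-5)
        assert fit.se == pytest.approx(ref.bse, abs=1e-5)

    def test_log_likelihood_nondecreasing(self):
        # re-run IRLS manually, tracking the likelihood path
        rng = np.random.default_rng(9)
        n = 300
        X = rng.normal(size=(n, 1))
        y = (rng.random(n) < expit(0.3 + 1.2 * X[:, 0])).astype(float)
        Xd = np.column_stack([np.ones(n), X])
        beta = np.zeros(2)
        lls = []
        for _ in range(25):
            eta = Xd @ beta
            mu = expit(eta)
            lls.append(float(np.sum(y * eta - np.logaddexp(0, eta))))
            w = np.clip(mu * (1 - mu), 1e-10, None)
            z = eta + (y - mu) / w
            beta = np.linalg.solve(Xd.T @ (Xd * w[:, None]), Xd.T @ (w * z))
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))
        fit = logistic_irls(X, y)
        assert fit.log_likelihood == pytest.approx(max(lls), abs=1e-6)

    def test_perfect_separation_detected(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 10.0, 11.0, 12.0, 13.0])
        y = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
        with pytest.raises(DegenerateDataError, match="separat"):
            logistic_irls(x[:, None], y)

    def test_rank_deficiency_detected(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=50)
        X = np.column_stack([x, 2 * x])
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(DiagnosticsError, match="rank"):
            logistic_irls(X, y)

    def test_single_class_outcome(self):
        with pytest.raises(DegenerateDataError):
            logistic_irls(np.arange(10.0)[:, None], np.zeros(10))


# ---------------------------------------------------------------------------
# power


class TestTwoProportionPower:
    def test_null_equals_alpha(self):
        assert two_proportion_power(0.3, 0.3, 100, 100) == pytest.approx(0.05, abs=5e-3)

    def test_large_effect(self):
        assert two_proportion_power(0.207, 0.675, 323, 77) > 0.99

    def test_monotone_in_effect_and_n(self):
        base = two_proportion_power(0.3, 0.45, 100, 100)
        assert two_proportion_power(0.3, 0.55, 100, 100) > base
        assert two_proportion_power(0.3, 0.45, 300, 300) > base

    def test_matches_simulation(self):
        # Monte-Carlo oracle for the same two-sided z-test decision rule
        p1, p2, n1, n2 = 0.25, 0.45, 80, 80
        rng = np.random.default_rng(11)
        reps = 20000
        x1 = rng.binomial(n1, p1, reps) / n1
        x2 = rng.binomial(n2, p2, reps) / n2
        pbar = (x1 * n1 + x2 * n2) / (n1 + n2)
        se0 = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
        z = np.abs(x1 - x2) / np.where(se0 == 0, np.inf, se0)
        sim_power = float(np.mean(z > stats.norm.ppf(0.975)))
        assert two_proportion_power(p1, p2, n1, n2) == pytest.approx(sim_power, abs=0.02)

    def test_invalid_inputs(self):
        with pytest.raises(DiagnosticsError):
            two_proportion_power(1.2, 0.5, 10, 10)
        with pytest.raises(DiagnosticsError):
            two_proportion_power(0.2, 0.5, 1, 10)
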