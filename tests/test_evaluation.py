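"""Evaluation statistics against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from avbrisk import DomainError, hazard_from_mortality
from avbrisk.evaluation import (
    backward_stepwise,
    brier,
    calibration_curve,
    confusion_metrics,
    cox_fit,
    delong_ci,
    delong_test,
    group_compare,
    hosmer_lemeshow,
    km_estimate,
    log_rank,
    r_squared,
    roc_auc,
    score_to_risk,
    youden_cutoff,
    youden_index,
)

from _oracles import (
    auc_by_enumeration,
    cox_binary_mle,
    hosmer_lemeshow_by_tabulation,
    km_by_product_limit,
    log_rank_by_tabulation,
    logistic_irls,
    youden_by_enumeration,
)


class TestGroupCompare:
    def test_identical_numeric_groups(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        _, _, p = group_compare(values, values)
        assert p == pytest.approx(1.0)

    def test_flat_contingency_table(self):
        name, stat, p = group_compare([[10, 10], [10, 10]])
        assert name == "chi_square"
        assert stat == 0.0
        assert p == 1.0

    def test_mortality_contrast_is_significant(self):
        # deaths/survivors split of a 181-vs-154 two-group cohort
        _, _, p = group_compare([[79, 102], [13, 141]])
        assert p < 0.001

    def test_routing_normal_vs_skewed(self, rng):
        normal = rng.normal(50, 5, 300)
        assert group_compare(normal[:150], normal[150:])[0] == "t_test"
        skewed = rng.lognormal(1, 1, 300)
        assert group_compare(skewed[:150], skewed[150:])[0] == "mann_whitney"

    def test_empty_group_rejected(self):
        with pytest.raises(DomainError):
            group_compare([1.0], [1.0, 2.0])


class TestKaplanMeier:
    def test_no_censoring_equals_binomial_survival(self):
        times = np.r_[np.linspace(1, 40, 79), np.full(102, 42.0)]
        events = np.r_[np.ones(79, bool), np.zeros(102, bool)]
        assert km_estimate(times, events, 42) == pytest.approx(1 - 79 / 181)

    def test_no_events(self):
        assert km_estimate([42.0] * 10, [False] * 10, 42) == 1.0

    def test_hand_product_limit_with_censoring(self):
        times, events = [1.0, 2.0, 3.0], [True, False, True]
        assert km_estimate(times, events, 3) == pytest.approx(0.0)
        assert km_estimate(times, events, 2.5) == pytest.approx(2 / 3)

    def test_matches_oracle_on_random_data(self, rng):
        times = rng.exponential(30, 200).clip(max=42)
        events = times < 42
        for at in (10, 20, 42):
            assert km_estimate(times, events, at) == pytest.approx(
                km_by_product_limit(times, events, at))


class TestLogRank:
    def test_identical_groups(self):
        times = [1.0, 2.0, 3.0, 4.0]
        events = [True, True, False, True]
        stat, p = log_rank(times + times, events + events, [0] * 4 + [1] * 4)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_tabulation(self):
        ta, ea = [1.0, 2.0, 3.0], [True, True, True]
        tb, eb = [4.0, 5.0, 6.0], [True, True, True]
        stat, _ = log_rank(ta + tb, ea + eb, [0, 0, 0, 1, 1, 1])
        assert stat == pytest.approx(log_rank_by_tabulation(ta, ea, tb, eb))

    def test_matches_hand_tabulation_with_censoring(self, rng):
        ta = rng.exponential(25, 80).clip(max=42)
        tb = rng.exponential(12, 90).clip(max=42)
        ea, eb = ta < 42, tb < 42
        stat, _ = log_rank(np.r_[ta, tb], np.r_[ea, eb], [0] * 80 + [1] * 90)
        assert stat == pytest.approx(log_rank_by_tabulation(ta, ea, tb, eb), rel=1e-9)

    def test_no_events_rejected(self):
        with pytest.raises(DomainError):
            log_rank([1.0, 2.0], [False, False], [0, 1])


class TestCox:
    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"time": [1, 2, 3, 4.0], "event": [1, 1, 0, 1], "x": [1.0] * 4})
        with pytest.raises(DomainError):
            cox_fit(df, ["x"])

    def test_six_subject_fit_matches_partial_likelihood_grid(self):
        df = pd.DataFrame({
            "time": [1.0, 2.5, 3.0, 4.5, 5.0, 6.5],
            "event": [1, 1, 0, 1, 1, 1],
            "x": [1.0, 1.0, 0.0, 0.0, 1.0, 0.0],
        })
        fit = cox_fit(df, ["x"])
        beta_oracle = cox_binary_mle(df["time"], df["event"].astype(bool), df["x"])
        assert fit.coef["x"] == pytest.approx(beta_oracle, abs=1e-6)
        assert fit.hazard_ratio["x"] == pytest.approx(np.exp(beta_oracle), abs=1e-5)
        assert fit.ci_low["x"] <= fit.hazard_ratio["x"] <= fit.ci_high["x"]

    def test_parameter_recovery_exponential_hazards(self, rng):
        """Known log-HR recovered within 3 Wald SEs at n = 5000."""
        n, beta = 5000, np.log(2.12)
        x = (rng.random(n) < 0.54).astype(float)
        base = hazard_from_mortality(0.084, 42.0)
        t = rng.exponential(1 / (base * np.exp(beta * x)))
        events = t < 42
        df = pd.DataFrame({"time": np.minimum(t, 42), "event": events.astype(int), "x": x})
        fit = cox_fit(df, ["x"])
        se = (np.log(fit.ci_high["x"]) - np.log(fit.ci_low["x"])) / (2 * 1.959964)
        assert abs(fit.coef["x"] - beta) < 3 * se


class TestBackwardStepwise:
    @staticmethod
    def _simulate(rng, n=250, strong=0.9):
        x_strong = rng.standard_normal(n)
        noise = rng.standard_normal((n, 3))
        t = rng.exponential(1 / (0.02 * np.exp(strong * x_strong)))
        events = t < 42
        return pd.DataFrame({
            "time": np.minimum(t, 42), "event": events.astype(int),
            "strong": x_strong, "n1": noise[:, 0], "n2": noise[:, 1], "n3": noise[:, 2],
        })

    def test_all_noise_yields_empty_model(self, rng):
        df = self._simulate(rng, strong=0.0).drop(columns=["strong"])
        final, _ = backward_stepwise(df, ["n1", "n2", "n3"])
        assert final.covariates == []

    def test_strong_covariate_is_retained(self):
        rng = np.random.default_rng(777)
        kept_strong = 0
        noise_kept = {"n1": 0, "n2": 0, "n3": 0}
        reps = 100
        for _ in range(reps):
            df = self._simulate(rng)
            final, _ = backward_stepwise(df, ["strong", "n1", "n2", "n3"])
            kept_strong += "strong" in final.covariates
            for k in noise_kept:
                noise_kept[k] += k in final.covariates
        assert kept_strong >= 0.95 * reps
        for k, count in noise_kept.items():
            assert count <= 0.20 * reps, (k, count)

    def test_elimination_matches_manual_backward_pass(self, rng):
        """The selected model equals an independently-driven elimination
        loop using the same univariate screen and Wald removals."""
        df = self._simulate(rng, n=400)
        candidates = ["strong", "n1", "n2", "n3"]
        final, univariate = backward_stepwise(df, candidates, alpha=0.05)

        retained = [c for c in candidates if univariate[c].p_value[c] < 0.05]
        while retained:
            fit = cox_fit(df, retained)
            worst = max(retained, key=lambda c: fit.p_value[c])
            if fit.p_value[worst] < 0.05:
                break
            retained.remove(worst)
        assert final.covariates == retained


class TestROC:
    def test_perfect_and_uninformative(self):
        assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_four_pair_enumeration(self):
        assert roc_auc([3, 5, 1, 4], [1, 1, 0, 0]) == 0.75

    def test_matches_enumeration_oracle_with_ties(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 21))
            scores = rng.integers(0, 5, n).astype(float)  # heavy ties
            y = rng.integers(0, 2, n).astype(bool)
            if y.all() or not y.any():
                continue
            assert roc_auc(scores, y) == pytest.approx(auc_by_enumeration(scores, y))

    def test_monotone_invariance_and_complement(self, rng):
        scores = rng.normal(size=100)
        y = rng.random(100) < 0.4
        auc = roc_auc(scores, y)
        assert roc_auc(np.exp(scores), y) == pytest.approx(auc)
        assert roc_auc(-scores, y) == pytest.approx(1 - auc)

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestDeLong:
    def test_score_vs_itself(self, rng):
        s = rng.normal(size=80)
        y = rng.random(80) < 0.5
        a1, a2, _, z, p = delong_test(s, s, y)
        assert a1 == a2
        assert z == 0.0 and p == 1.0

    def test_monotone_transform_is_equivalent(self, rng):
        s = rng.normal(size=80)
        y = rng.random(80) < 0.5
        a1, a2, _, _, p = delong_test(s, np.tanh(s), y)
        assert a1 == pytest.approx(a2)
        assert p == 1.0

    def test_ci_brackets_auc_and_detects_signal(self, rng):
        y = rng.random(300) < 0.4
        s = y + rng.normal(0, 1, 300)
        auc, var, (lo, hi) = delong_ci(s, y)
        assert lo < auc < hi
        assert var > 0
        assert lo > 0.5  # informative score

    def test_variance_agrees_with_bootstrap(self, rng):
        """DeLong single-AUC variance within 10% of a 10,000-rep bootstrap."""
        n = 200
        y = np.r_[np.ones(80, bool), np.zeros(120, bool)]
        s = y + rng.normal(0, 1.2, n)
        _, var_delong, _ = delong_ci(s, y)
        from scipy.stats import rankdata
        aucs = np.empty(10_000)
        for b in range(10_000):
            idx = rng.integers(0, n, n)
            yb, sb = y[idx], s[idx]
            n1 = yb.sum()
            if n1 == 0 or n1 == n:
                aucs[b] = np.nan
                continue
            ranks = rankdata(sb)
            aucs[b] = (ranks[yb].sum() - n1 * (n1 + 1) / 2) / (n1 * (n - n1))
        var_boot = np.nanvar(aucs, ddof=1)
        assert var_delong == pytest.approx(var_boot, rel=0.10)


class TestYouden:
    def test_reported_operating_point(self):
        assert round(youden_index(0.671, 0.706), 2) == 0.38

    def test_perfect_separation(self):
        cutoff, j, sens, spec = youden_cutoff([1, 2, 8, 9], [0, 0, 1, 1])
        assert (j, sens, spec) == (1.0, 1.0, 1.0)
        assert cutoff == 8  # smallest cutoff achieving maximal J

    def test_small_set_matches_enumeration(self):
        got = youden_cutoff([3, 5, 1, 4], [1, 1, 0, 0])
        assert got == youden_by_enumeration([3, 5, 1, 4], [1, 1, 0, 0])

    def test_random_sets_match_enumeration(self, rng):
        for _ in range(20):
            s = rng.integers(0, 8, 30).astype(float)
            y = rng.random(30) < 0.4
            if y.all() or not y.any():
                continue
            got = youden_cutoff(s, y)
            exp = youden_by_enumeration(s, y)
            assert got[0] == exp[0]
            assert got[1] == pytest.approx(exp[1])


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        assert confusion_metrics([1, 2, 8, 9], [0, 0, 1, 1], 5) == (1, 1, 1, 1)

    def test_cutoff_below_all_scores(self):
        with pytest.warns(RuntimeWarning, match="NPV undefined"):
            sens, spec, ppv, npv = confusion_metrics([3, 5, 1, 4], [1, 1, 0, 0], 0.5)
        assert (sens, spec) == (1.0, 0.0)
        assert np.isnan(npv)  # empty predicted-negative margin is flagged

    def test_hand_counts(self):
        # TP 55, FN 24, TN 72, FP 30
        scores = np.r_[np.ones(55), np.zeros(24), np.ones(30), np.zeros(72)]
        y = np.r_[np.ones(79, bool), np.zeros(102, bool)]
        sens, spec, ppv, npv = confusion_metrics(scores, y, 0.5)
        assert sens == pytest.approx(0.696, abs=5e-4)
        assert spec == pytest.approx(0.706, abs=5e-4)
        assert ppv == pytest.approx(0.647, abs=5e-4)
        assert npv == pytest.approx(0.750, abs=5e-4)


class TestScoreToRisk:
    def test_uninformative_score_gives_prevalence(self, rng):
        s = rng.normal(size=400)
        y = rng.random(400) < 0.3
        risk = score_to_risk(s, y)
        assert np.allclose(risk.probabilities, y.mean(), atol=0.05)

    def test_mean_probability_equals_event_rate(self, rng):
        s = rng.normal(size=300)
        y = (s + rng.normal(0, 1, 300)) > 0.5
        risk = score_to_risk(s, y)
        assert risk.probabilities.mean() == pytest.approx(y.mean(), abs=1e-8)

    def test_matches_independent_irls(self, rng):
        s = rng.normal(size=250)
        y = (s + rng.normal(0, 2, 250)) > 0.3
        risk = score_to_risk(s, y)
        b0, b1 = logistic_irls(s, y)
        assert risk.intercept == pytest.approx(b0, abs=1e-6)
        assert risk.slope == pytest.approx(b1, abs=1e-6)

    def test_separation_is_flagged_and_clamped(self, rng):
        s = np.r_[np.zeros(20), np.ones(20)]
        y = s > 0.5
        with pytest.warns(RuntimeWarning):
            risk = score_to_risk(s, y)
        assert risk.separation
        assert (risk.probabilities > 0).all() and (risk.probabilities < 1).all()


class TestHosmerLemeshow:
    def test_exact_agreement_gives_zero(self):
        p = np.r_[np.full(10, 0.2), np.full(10, 0.8)]
        y = np.r_[np.ones(2), np.zeros(8), np.ones(8), np.zeros(2)]
        stat, pval = hosmer_lemeshow(p, y, groups=2)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert pval == pytest.approx(1.0)

    def test_matches_hand_tabulation_on_miscalibrated_data(self, rng):
        p = rng.random(200)
        y = rng.random(200) < p ** 2  # deliberately miscalibrated
        stat, _ = hosmer_lemeshow(p, y, groups=10)
        order = np.argsort(p, kind="stable")
        chunks = np.array_split(order, 10)
        expected = hosmer_lemeshow_by_tabulation(
            [p[c] for c in chunks], [y[c] for c in chunks])
        assert stat == pytest.approx(expected, rel=1e-12)

    def test_insufficient_data_rejected(self):
        with pytest.raises(DomainError):
            hosmer_lemeshow([0.5] * 5, [1, 0, 1, 0, 1], groups=10)


class TestOverallPerformance:
    def test_brier_values(self):
        assert brier([0.5] * 4, [1, 0, 1, 0]) == 0.25
        assert brier([1.0, 0.0], [1, 0]) == 0.0
        assert brier([0.8, 0.4], [1, 0]) == pytest.approx(0.10)

    def test_nagelkerke_near_zero_when_uninformative(self, rng):
        y = rng.random(500) < 0.3
        p = np.full(500, y.mean())
        assert r_squared(p, y) == pytest.approx(0.0, abs=1e-10)

    def test_nagelkerke_matches_model_likelihood_formula(self, rng):
        s = rng.normal(size=300)
        y = (s + rng.normal(0, 1, 300)) > 0.2
        risk = score_to_risk(s, y)
        p = risk.probabilities
        n = len(y)
        ll1 = np.sum(np.where(y, np.log(p), np.log1p(-p)))
        prev = y.mean()
        ll0 = n * (prev * np.log(prev) + (1 - prev) * np.log1p(-prev))
        expected = (1 - np.exp(2 * (ll0 - ll1) / n)) / (1 - np.exp(2 * ll0 / n))
        assert r_squared(p, y) == pytest.approx(expected, abs=1e-10)
        assert 0 < r_squared(p, y) < 1

    def test_calibration_conservation(self, rng):
        p = rng.random(300)
        y = rng.random(300) < p
        bins = calibration_curve(p, y, bins=10)
        weighted = sum(rate * n for _, rate, n in bins) / sum(n for _, _, n in bins)
        assert weighted == pytest.approx(y.mean())

    def test_constant_probability_collapses_to_prevalence(self, rng):
        y = rng.random(100) < 0.3
        bins = calibration_curve(np.full(100, 0.3), y, bins=5)
        for mean_p, _, _ in bins:
            assert mean_p == pytest.approx(0.3)
        weighted = sum(rate * n for _, rate, n in bins) / 100
        assert weighted == pytest.approx(y.mean())
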