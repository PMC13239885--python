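"""Kaplan–Meier, log-rank, maximally selected cutpoints and Cox fits."""

import numpy as np
import pandas as pd
import pytest

from nichesig.datasets import ValidationError
from nichesig.experiments import cutpoint_oracle_study
from nichesig.survival import (
    ConvergenceError,
    MonotoneLikelihoodError,
    cox_fit,
    km_estimate,
    logrank_test,
    optimal_cutpoint,
    univariate_cox_screen,
)
from nichesig.synthetic import SimBulkConfig, generate_bulk_cohort


class TestKaplanMeier:
    def test_single_subject_event(self):
        km = km_estimate([5.0], [1])
        assert km.survival_at(5.0) == 0.0
        assert km.survival_at(4.9) == 1.0

    def test_all_censored_stays_at_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert np.all(km.survival == 1.0)

    def test_hand_product_limit(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert km.survival_at(1.0) == pytest.approx(2 / 3)
        assert km.survival_at(2.5) == pytest.approx(2 / 3)
        assert km.survival_at(3.0) == pytest.approx(0.0)

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5.0, size=60) + 0.01
        km = km_estimate(t, np.ones(60))
        for u in km.times:
            assert km.survival_at(u) == pytest.approx(np.mean(t > u))

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([-1.0, 2.0], [1, 1])


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 0, 1, 1, 0, 1]
        g = [0, 0, 0, 1, 1, 1]
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_subject_hand_computation(self):
        """One informative risk set: O-E = 0.5, Var = 0.25, chi2 = 1."""
        chi2, p = logrank_test([1.0, 2.0], [1, 1], [0, 1])
        assert chi2 == pytest.approx(1.0)

    def test_invariant_to_increasing_time_transform(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(3.0, 40) + 0.01
        e = (rng.random(40) < 0.7).astype(int)
        g = (rng.random(40) < 0.5).astype(int)
        chi2_a, _ = logrank_test(t, e, g)
        chi2_b, _ = logrank_test(np.exp(t / 4), e, g)
        assert chi2_a == pytest.approx(chi2_b)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank
        rng = np.random.default_rng(2)
        for _ in range(10):
            t = rng.exponential(3.0, 50) + 0.01
            e = (rng.random(50) < 0.8).astype(int)
            g = (rng.random(50) < 0.5).astype(int)
            chi2, p = logrank_test(t, e, g)
            ref = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
            assert chi2 == pytest.approx(ref.test_statistic, rel=1e-8)
            assert p == pytest.approx(ref.p_value, rel=1e-8)

    def test_one_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([1.0, 2.0], [1, 1], [0, 0])


class TestOptimalCutpoint:
    def test_recovers_planted_threshold(self):
        """Events concentrated above score 5 with earlier times: cut in (5, 6)."""
        scores = np.arange(1.0, 11.0)
        time = np.where(scores > 5, 2.0, 20.0) + np.linspace(0, 0.5, 10)
        event = (scores > 5).astype(int)
        res = optimal_cutpoint(scores, time, event, minprop=0.1)
        assert 5.0 < res.cutpoint < 6.0
        assert res.selection_biased

    def test_constant_scores_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            optimal_cutpoint(np.ones(20), np.arange(1.0, 21.0), np.ones(20))

    def test_equals_bruteforce_enumeration(self):
        res = cutpoint_oracle_study(n_instances=25, n=40, seed=0)
        assert res["agreement_frac"] == 1.0

    def test_permutation_p_is_seeded_and_sane(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40)
        t = rng.exponential(5, 40) + 0.01
        e = np.ones(40, dtype=int)
        a = optimal_cutpoint(scores, t, e, n_permutations=50, seed=9)
        b = optimal_cutpoint(scores, t, e, n_permutations=50, seed=9)
        assert a.permutation_p == b.permutation_p
        assert 0.0 < a.permutation_p <= 1.0
        assert a.permutation_p >= a.p - 1e-12  # selection bias correction never shrinks p


class TestCoxFit:
    def test_negating_covariate_negates_coefficient(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=80)
        t = rng.exponential(np.exp(-0.5 * x)) + 0.01
        e = np.ones(80, dtype=int)
        f1 = cox_fit(pd.DataFrame({"x": x}), t, e)
        f2 = cox_fit(pd.DataFrame({"x": -x}), t, e)
        assert f1.coef[0] == pytest.approx(-f2.coef[0], abs=1e-10)

    def test_loglik_improves_over_null(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        t = rng.exponential(np.exp(-0.7 * x)) + 0.01
        fit = cox_fit(pd.DataFrame({"x": x}), t, np.ones(60))
        assert fit.loglik >= fit.loglik_null

    def test_matches_lifelines_with_ties(self):
        """Efron-corrected coefficients agree with lifelines to 1e-6."""
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(6)
        for _ in range(5):
            n = 100
            x = rng.normal(size=(n, 3))
            lp = x @ np.array([0.5, -0.3, 0.0])
            t = np.ceil(rng.exponential(np.exp(-lp)) * 4) / 4  # heavy ties
            e = (rng.random(n) < 0.8).astype(int)
            df = pd.DataFrame(x, columns=["a", "b", "c"])
            fit = cox_fit(df, t, e, scale_covariates=False)
            ll = CoxPHFitter()
            ll.fit(df.assign(time=t, event=e), "time", "event",
                   fit_options={"precision": 1e-9})
            assert np.allclose(fit.coef, ll.params_.to_numpy(), atol=1e-6)
            assert np.allclose(fit.se, ll.standard_errors_.to_numpy(), atol=1e-6)

    def test_binary_covariates_not_standardised(self):
        rng = np.random.default_rng(7)
        x = (rng.random(100) < 0.4).astype(float)
        t = rng.exponential(np.exp(-0.8 * x)) + 0.01
        scaled = cox_fit(pd.DataFrame({"b": x}), t, np.ones(100), scale_covariates=True)
        raw = cox_fit(pd.DataFrame({"b": x}), t, np.ones(100), scale_covariates=False)
        assert scaled.coef[0] == pytest.approx(raw.coef[0], abs=1e-10)

    def test_perfect_separation_detected(self):
        x = np.arange(20.0)
        t = np.linspace(20, 1, 20)  # risk strictly increases with x
        with pytest.raises(MonotoneLikelihoodError):
            cox_fit(pd.DataFrame({"x": x}), t, np.ones(20))

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            cox_fit(pd.DataFrame({"x": np.ones(30)}),
                    np.arange(1.0, 31.0), np.ones(30))


class TestUnivariateScreen:
    def test_screen_equals_individual_fits(self, bulk_cohort):
        _, cohort = bulk_cohort
        genes = list(cohort.expression.columns[:3])
        screen = univariate_cox_screen(cohort, genes)
        for g in genes:
            single = cox_fit(cohort.expression[[g]],
                             cohort.clinical["time"], cohort.clinical["event"])
            assert screen.loc[g, "coef"] == pytest.approx(single.coef[0], abs=1e-10)

    def test_planted_hazard_gene_flagged_risk(self, bulk_cohort):
        cfg, cohort = bulk_cohort
        screen = univariate_cox_screen(cohort, [cfg.signature[0]])
        row = screen.iloc[0]
        assert row["direction"] == "risk"
        assert row["p"] < 0.05

    def test_null_screen_calibration(self):
        """Pure-noise genes reject at about the nominal 5% rate."""
        cfg = SimBulkConfig(n_samples=100, n_genes=400, signature=("SIG000",),
                            log_hr_per_sd=0.0, seed=8)
        cohort = generate_bulk_cohort(cfg)
        noise_genes = [g for g in cohort.expression.columns if g.startswith("B")]
        screen = univariate_cox_screen(cohort, noise_genes)
        rate = (screen["p"] < 0.05).mean()
        assert 0.02 <= rate <= 0.09
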