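import math

import numpy as np
import pytest
from scipy import optimize

from survrank.cox_ph import (fit_cox, fit_cox_arrays, interpret_hr,
                             partial_loglik, partial_loglik_arrays,
                             univariate_screen)
from survrank.io_preprocess import Cohort, SurvivalRecord
from survrank.kaplan_meier import logrank_test
from survrank.synthetic_cohort import (FactorSpec, SimulationConfig,
                                       generate_arrays, generate_cohort)


def small_random_cohort(rng, n=12, p=2, tie_prob=0.3):
    t = rng.exponential(10, n)
    if tie_prob:
        t = np.where(rng.random(n) < tie_prob, np.round(t), t) + 0.5
    e = rng.integers(0, 2, n)
    if e.sum() == 0:
        e[0] = 1
    X = rng.integers(0, 2, (n, p)).astype(float)
    X += rng.normal(0, 0.01, (n, p))  # avoid accidental constant columns
    return t, e, X


class TestPartialLoglik:
    def test_single_subject_loglik_zero(self):
        ll, grad, _ = partial_loglik_arrays([5.0], [1], [[1.0]], [0.7])
        assert ll == pytest.approx(0.0)
        assert grad[0] == pytest.approx(0.0)

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_gradient_matches_central_differences(self, ties):
        rng = np.random.default_rng(12)
        h = 1e-6
        for _ in range(8):
            t, e, X = small_random_cohort(rng)
            b = rng.normal(0, 0.5, 2)
            ll, grad, neg_hess = partial_loglik_arrays(t, e, X, b, ties=ties)
            for j in range(2):
                bp, bm = b.copy(), b.copy()
                bp[j] += h
                bm[j] -= h
                lp = partial_loglik_arrays(t, e, X, bp, ties=ties)[0]
                lm = partial_loglik_arrays(t, e, X, bm, ties=ties)[0]
                assert grad[j] == pytest.approx((lp - lm) / (2 * h), abs=1e-5)
                gp = partial_loglik_arrays(t, e, X, bp, ties=ties)[1][j]
                gm = partial_loglik_arrays(t, e, X, bm, ties=ties)[1][j]
                assert -neg_hess[j, j] == pytest.approx((gp - gm) / (2 * h),
                                                        abs=1e-4)

    def test_gradient_at_zero_is_logrank_score(self):
        # for one binary covariate the score at b=0 is O - E of the log-rank
        rng = np.random.default_rng(14)
        t = np.round(rng.exponential(10, 60), 0) + 1.0
        e = rng.integers(0, 2, 60)
        x = rng.integers(0, 2, 60).astype(float)
        _, grad, _ = partial_loglik_arrays(t, e, x[:, None], [0.0])
        res = logrank_test((t[x == 0], e[x == 0]), (t[x == 1], e[x == 1]))
        assert grad[0] == pytest.approx(res.observed[1] - res.expected[1],
                                        abs=1e-10)

    def test_score_test_equals_logrank_chi_square(self):
        # exact identity requires distinct event times: with ties the
        # hypergeometric variance carries a multiplicity correction that the
        # Breslow information does not
        rng = np.random.default_rng(16)
        for _ in range(10):
            t = rng.exponential(10, 50)
            e = rng.integers(0, 2, 50)
            x = rng.integers(0, 2, 50).astype(float)
            if e.sum() == 0 or len(set(x)) < 2:
                continue
            _, grad, neg_hess = partial_loglik_arrays(t, e, x[:, None], [0.0])
            score_chi2 = grad[0] ** 2 / neg_hess[0, 0]
            res = logrank_test((t[x == 0], e[x == 0]), (t[x == 1], e[x == 1]))
            assert score_chi2 == pytest.approx(res.chi_square, abs=1e-8)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            partial_loglik_arrays([1.0, 2.0], [0, 0], [[0.0], [1.0]], [0.0])

    def test_constant_covariate_flagged_inestimable(self):
        with pytest.raises(ValueError, match="inestimable"):
            partial_loglik_arrays([1.0, 2.0], [1, 1], [[1.0], [1.0]], [0.0],
                                  names=["asa"])


class TestFitCox:
    def test_exchangeable_groups_give_null_coefficient(self):
        # the two covariate levels carry identical event-time patterns
        times = [3, 6, 9, 3, 6, 9]
        events = [1, 1, 0, 1, 1, 0]
        x = [0, 0, 0, 1, 1, 1]
        fit = fit_cox_arrays(times, events, np.array(x, float)[:, None], ["g"])
        assert fit.converged
        assert fit.b[0] == pytest.approx(0.0, abs=1e-12)
        assert fit.exp_b[0] == pytest.approx(1.0)

    def test_brute_force_partial_likelihood_maximizer(self):
        rng = np.random.default_rng(18)
        for _ in range(15):
            t, e, X = small_random_cohort(rng, n=8, p=1, tie_prob=0.4)
            fit = fit_cox_arrays(t, e, X, ["x"])
            if not fit.converged or abs(fit.b[0]) > 4.5:
                continue  # no interior maximum to compare against
            neg = lambda b: -partial_loglik_arrays(t, e, X, [b])[0]
            brute = optimize.minimize_scalar(neg, bounds=(-5, 5),
                                             method="bounded",
                                             options={"xatol": 1e-10})
            assert fit.b[0] == pytest.approx(brute.x, abs=1e-6)

    def test_parameter_recovery_single_factor(self):
        cfg = SimulationConfig(
            n=10000, factors=(FactorSpec("x", 0.5, math.log(1.79)),),
            baseline_rate=0.0173, censor_admin=500.0, censor_rate=1 / 300,
            seed=19)
        t, e, X = generate_arrays(cfg)
        fit = fit_cox_arrays(t, e, X, ["x"])
        assert fit.b[0] == pytest.approx(math.log(1.79), abs=0.05)

    def test_wald_inference_internally_consistent(self):
        rng = np.random.default_rng(20)
        t, e, X = small_random_cohort(rng, n=60, p=2, tie_prob=0.0)
        fit = fit_cox_arrays(t, e, X, ["a", "b"])
        np.testing.assert_allclose(fit.exp_b, np.exp(fit.b))
        np.testing.assert_allclose(fit.ci_lower,
                                   np.exp(fit.b - 1.959964 * fit.se), rtol=1e-5)
        assert (fit.ci_lower < fit.exp_b).all()
        assert (fit.exp_b < fit.ci_upper).all()
        np.testing.assert_allclose(fit.wald_z, fit.b / fit.se)

    def test_time_rescaling_leaves_coefficients_unchanged(self):
        rng = np.random.default_rng(22)
        t, e, X = small_random_cohort(rng, n=40)
        fit1 = fit_cox_arrays(t, e, X, ["a", "b"])
        fit2 = fit_cox_arrays(t * 12.0, e, X, ["a", "b"])
        np.testing.assert_allclose(fit1.b, fit2.b, atol=1e-8)

    def test_relabeling_binary_covariate_flips_sign(self):
        rng = np.random.default_rng(24)
        t = rng.exponential(10, 50)
        e = rng.integers(0, 2, 50)
        x = rng.integers(0, 2, 50).astype(float)
        e[0] = 1
        fit1 = fit_cox_arrays(t, e, x[:, None], ["x"])
        fit2 = fit_cox_arrays(t, e, (1 - x)[:, None], ["x"])
        assert fit1.b[0] == pytest.approx(-fit2.b[0], abs=1e-8)

    def test_breslow_and_efron_agree_without_ties(self):
        rng = np.random.default_rng(26)
        t, e, X = small_random_cohort(rng, n=50, tie_prob=0.0)
        fb = fit_cox_arrays(t, e, X, ["a", "b"], ties="breslow")
        fe = fit_cox_arrays(t, e, X, ["a", "b"], ties="efron")
        np.testing.assert_allclose(fb.b, fe.b, atol=1e-10)
        np.testing.assert_allclose(fb.se, fe.se, atol=1e-10)

    def test_efron_matches_lifelines_with_ties(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        rng = np.random.default_rng(28)
        t, e, X = small_random_cohort(rng, n=120, p=3, tie_prob=0.5)
        df = pd.DataFrame(X, columns=list("abc"))
        df["t"], df["e"] = t, e
        cph = lifelines.CoxPHFitter().fit(df, "t", "e", formula="a + b + c")
        fit = fit_cox_arrays(t, e, X, list("abc"), ties="efron")
        np.testing.assert_allclose(fit.b, cph.params_.values, atol=1e-5)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.values,
                                   atol=1e-5)

    def test_separation_flagged_not_silent(self):
        # all unfavorable subjects die before any favorable follow-up begins
        t = np.array([1, 2, 3, 10, 11, 12], float)
        e = np.array([1, 1, 1, 1, 1, 1])
        x = np.array([1, 1, 1, 0, 0, 0], float)
        fit = fit_cox_arrays(t, e, x[:, None], ["x"])
        assert (not fit.converged) or fit.b[0] > 5
        if not fit.converged:
            assert fit.message

    def test_more_covariates_than_events_rejected(self):
        t = np.array([1.0, 2.0, 3.0])
        e = np.array([1, 0, 0])
        X = np.array([[0, 1], [1, 0], [1, 1]], float)
        with pytest.raises(ValueError, match="overparameterized"):
            fit_cox_arrays(t, e, X, ["a", "b"])


class TestCohortInterface:
    def _cohort(self):
        rng = np.random.default_rng(30)
        recs = [
            SurvivalRecord(f"s{i}", float(rng.exponential(10) + 0.1),
                           int(rng.integers(0, 2)),
                           {"a": int(rng.integers(0, 2)),
                            "b": int(rng.integers(0, 2))})
            for i in range(60)
        ]
        return Cohort(recs)

    def test_partial_loglik_cohort_wrapper(self):
        cohort = self._cohort()
        ll, grad, neg_hess = partial_loglik(cohort, ["a", "b"], [0.1, -0.2])
        ll2, *_ = partial_loglik_arrays(cohort.times(), cohort.events(),
                                        cohort.covariate_matrix(["a", "b"]),
                                        [0.1, -0.2])
        assert ll == pytest.approx(ll2)
        assert grad.shape == (2,) and neg_hess.shape == (2, 2)

    def test_univariate_screen_identical_columns_identical_fits(self):
        cohort = self._cohort()
        recs = [SurvivalRecord(r.subject_id, r.time, r.event,
                               {**r.covariates, "a2": r.covariates["a"]})
                for r in cohort.records]
        fits = univariate_screen(Cohort(recs), ["a", "a2"])
        np.testing.assert_allclose(fits["a"].b, fits["a2"].b)
        np.testing.assert_allclose(fits["a"].se, fits["a2"].se)

    def test_univariate_screen_isolates_per_factor_failures(self):
        recs = [SurvivalRecord(f"s{i}", float(i + 1), 1,
                               {"good": i % 2, "constant": 1})
                for i in range(20)]
        fits = univariate_screen(Cohort(recs), ["good", "constant"])
        assert fits["good"].converged
        assert not fits["constant"].converged
        assert "inestimable" in fits["constant"].message

    def test_univariate_screen_empty_factor_list(self):
        assert univariate_screen(self._cohort(), []) == {}

    def test_multivariate_enter_uses_all_factors(self, study_cohort):
        names = list(study_cohort.variables)
        fit = fit_cox(study_cohort, names)
        assert fit.converged
        assert set(fit.names) == set(names)


class TestInterpretHR:
    @pytest.mark.parametrize("hr, pct", [(1.15, 15), (1.0, 0), (1.79, 79),
                                         (2.04, 104), (0.982, -2)])
    def test_percent_excess_hazard(self, hr, pct):
        assert interpret_hr(hr) == pct

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            interpret_hr(0.0)
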