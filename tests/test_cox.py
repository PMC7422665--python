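import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gapsurv import (
    ConvergenceError,
    CoxData,
    CoxModelSpec,
    GapsurvError,
    MCMCSettings,
    PriorSpec,
    cox_data_from_cohort,
    fit_bayes,
    fit_mle,
    partial_loglik,
    simulate_ph_data,
    simulate_crossing_hazard_data,
    supremum_ph_test,
)


def brute_force_breslow(beta, times, events, X):
    """Term-by-term partial likelihood over explicit risk sets."""
    beta = np.atleast_1d(beta)
    X = np.atleast_2d(X)
    if X.shape[0] != len(times):
        X = X.T
    ll = 0.0
    for i in range(len(times)):
        if events[i] == 1:
            risk = [j for j in range(len(times)) if times[j] >= times[i]]
            ll += float(X[i] @ beta)
            ll -= math.log(sum(math.exp(float(X[j] @ beta)) for j in risk))
    return ll


def small_data(rng, n=6, p=1):
    t = rng.exponential(10, n)
    d = (rng.random(n) < 0.8).astype(int)
    d[0] = 1  # ensure at least one event
    X = rng.standard_normal((n, p))
    return CoxData(times=t, events=d, X=X, names=tuple(f"x{i}" for i in range(p)))


class TestPartialLikelihood:
    def test_zero_beta_counts_risk_sets(self):
        data = CoxData(
            times=np.array([1.0, 2.0, 3.0]),
            events=np.array([1, 1, 1]),
            X=np.array([[0.3], [1.2], [-0.5]]),
            names=("x",),
        )
        expected = -(math.log(3) + math.log(2) + math.log(1))
        assert partial_loglik(np.zeros(1), data) == pytest.approx(expected)

    def test_zero_beta_with_ties_breslow(self):
        data = CoxData(
            times=np.array([1.0, 1.0, 2.0]),
            events=np.array([1, 1, 1]),
            X=np.zeros((3, 1)),
            names=("x",),
        )
        # both tied events see the full risk set of 3 under Breslow
        assert partial_loglik(np.zeros(1), data) == pytest.approx(
            -(math.log(3) + math.log(3) + math.log(1))
        )

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            data = small_data(rng, n=4)
            beta = np.array([0.5])
            assert partial_loglik(beta, data) == pytest.approx(
                brute_force_breslow(beta, data.times, data.events, data.X),
                abs=1e-10,
            )

    @settings(max_examples=50, deadline=None)
    @given(shift=st.floats(-5, 5, allow_nan=False))
    def test_covariate_location_invariance(self, shift):
        rng = np.random.default_rng(4)
        t = rng.exponential(10, 8)
        d = np.ones(8, int)
        X = rng.standard_normal((8, 1))
        beta = np.array([0.7])
        a = partial_loglik(beta, CoxData(times=t, events=d, X=X, names=("x",)))
        b = partial_loglik(
            beta, CoxData(times=t, events=d, X=X + shift, names=("x",))
        )
        assert a == pytest.approx(b, abs=1e-8)

    def test_no_events_rejected(self):
        with pytest.raises(GapsurvError):
            CoxData(
                times=np.array([1.0, 2.0]), events=np.array([0, 0]),
                X=np.zeros((2, 1)), names=("x",),
            )

    def test_concavity_numeric_hessian(self, rng):
        data = small_data(rng, n=10)
        h = 1e-4
        for _ in range(5):
            b = rng.normal(scale=0.8, size=1)
            f = lambda v: partial_loglik(np.array([v]), data)
            second = (f(b[0] + h) - 2 * f(b[0]) + f(b[0] - h)) / h**2
            assert second <= 1e-6

    def test_efron_equals_breslow_without_ties(self, rng):
        t = rng.exponential(5, 10)
        d = np.ones(10, int)
        X = rng.standard_normal((10, 1))
        b = np.array([0.4])
        lb = partial_loglik(b, CoxData(times=t, events=d, X=X, names=("x",)))
        le = partial_loglik(
            b, CoxData(times=t, events=d, X=X, names=("x",), ties_method="efron")
        )
        assert lb == pytest.approx(le, abs=1e-10)


class TestMLE:
    def test_equals_grid_search_on_toy_data(self, rng):
        data = small_data(rng, n=6)
        fit = fit_mle(data)
        grid = np.linspace(fit.coefficients[0] - 1, fit.coefficients[0] + 1, 20001)
        vals = [partial_loglik(np.array([b]), data) for b in grid]
        assert abs(grid[int(np.argmax(vals))] - fit.coefficients[0]) < 1e-3

    def test_matches_statsmodels_breslow(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        t, d, X = simulate_ph_data(300, np.array([-0.4, 0.2]), rng,
                                   censor_quantile=0.8)
        data = CoxData(times=t, events=d, X=X, names=("arm", "z"))
        fit = fit_mle(data)
        ref = sm.PHReg(t, X, status=d, ties="breslow").fit()
        assert np.allclose(fit.coefficients, ref.params, atol=1e-6)

    def test_parameter_recovery_large_n(self, rng):
        t, d, X = simulate_ph_data(2000, -0.3, rng, censor_quantile=0.85)
        fit = fit_mle(CoxData(times=t, events=d, X=X, names=("arm",)))
        se = math.sqrt(fit.covariance[0, 0])
        assert abs(fit.coefficients[0] - (-0.3)) < 3 * se

    def test_monotone_likelihood_detected(self):
        # covariate perfectly orders the event times: likelihood is monotone
        t = np.arange(1.0, 11.0)
        d = np.ones(10, int)
        x = np.arange(10.0)[:, None]
        with pytest.raises(ConvergenceError):
            fit_mle(CoxData(times=t, events=d, X=x, names=("x",)))

    def test_too_few_events_rejected(self, rng):
        t = np.array([1.0, 2.0, 3.0])
        d = np.array([1, 0, 0])
        X = rng.standard_normal((3, 2))
        with pytest.raises(GapsurvError, match="events"):
            fit_mle(CoxData(times=t, events=d, X=X, names=("a", "b")))

    def test_cohort_extraction_standardizes_age(self, default_cohort):
        cohort, _ = default_cohort
        data = cox_data_from_cohort(cohort, CoxModelSpec(endpoint="pfs"))
        age = data.X[:, list(data.names).index("age")]
        assert abs(age.mean()) < 1e-10 and age.std(ddof=1) == pytest.approx(1.0)


class TestBayes:
    def test_vague_prior_tracks_mle(self, rng, fast_mcmc):
        t, d, X = simulate_ph_data(600, np.array([-0.3, 0.3]), rng,
                                   censor_quantile=0.9)
        data = CoxData(times=t, events=d, X=X, names=("arm", "z"))
        mle = fit_mle(data)
        bay = fit_bayes(data, PriorSpec(), fast_mcmc)
        se = np.sqrt(np.diag(mle.covariance))
        assert np.all(np.abs(bay.coefficients - mle.coefficients) < 0.5 * se)

    def test_tight_prior_dominates(self, rng, fast_mcmc):
        t, d, X = simulate_ph_data(200, 0.8, rng)
        data = CoxData(times=t, events=d, X=X, names=("arm",))
        bay = fit_bayes(
            data, PriorSpec(value=1e-6, interpretation="variance"), fast_mcmc
        )
        assert abs(bay.coefficients[0]) < 0.01

    def test_acceptance_rate_in_tuned_band(self, rng, fast_mcmc):
        t, d, X = simulate_ph_data(300, -0.2, rng)
        data = CoxData(times=t, events=d, X=X, names=("arm",))
        bay = fit_bayes(data, PriorSpec(), fast_mcmc)
        for rate in bay.draws.acceptance.values():
            assert 0.1 < rate < 0.65

    def test_dic_penalises_parameters_near_their_count(self, rng, fast_mcmc):
        t, d, X = simulate_ph_data(400, np.array([-0.3, 0.2]), rng)
        data = CoxData(times=t, events=d, X=X, names=("arm", "z"))
        bay = fit_bayes(data, PriorSpec(), fast_mcmc)
        assert 0.5 < bay.summary.p_d < 4.0


class TestSupremumTest:
    def test_fixed_seed_reproducible(self, rng):
        t, d, X = simulate_ph_data(200, 0.4, rng)
        data = CoxData(times=t, events=d, X=X, names=("arm",))
        fit = fit_mle(data)
        p1 = supremum_ph_test(fit, data, n_resample=300, seed=5)
        p2 = supremum_ph_test(fit, data, n_resample=300, seed=5)
        assert p1 == p2

    def test_requires_mle_fit_and_enough_resamples(self, rng, fast_mcmc):
        t, d, X = simulate_ph_data(150, 0.4, rng)
        data = CoxData(times=t, events=d, X=X, names=("arm",))
        fit = fit_mle(data)
        with pytest.raises(GapsurvError):
            supremum_ph_test(fit, data, n_resample=50, seed=1)
        bay = fit_bayes(data, PriorSpec(), fast_mcmc)
        with pytest.raises(GapsurvError):
            supremum_ph_test(bay, data, n_resample=300, seed=1)

    def test_power_against_crossing_hazard(self):
        # effect reverses sign at the baseline median: should be detected
        rng = np.random.default_rng(13)
        rejections = 0
        for i in range(20):
            t, d, X = simulate_crossing_hazard_data(500, 0.8, tau=69.3, rng=rng)
            data = CoxData(times=t, events=d, X=X, names=("x",))
            p = supremum_ph_test(fit_mle(data), data, n_resample=200,
                                 seed=500 + i)["x"]
            rejections += p < 0.05
        assert rejections / 20 > 0.5
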