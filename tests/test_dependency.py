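import numpy as np
import pytest

from gapsurv import (
    Cohort,
    GapsurvError,
    MCMCSettings,
    PriorSpec,
    SyntheticParams,
    arm_effect_difference,
    combined_arm_inference,
    fit_aft_bayes,
    fit_gap_regression,
    gap_matrix,
    generate_cohort,
    predict_next_gap,
)
from gapsurv.bayes_linear import posterior_mean_known_scale
from conftest import make_record


def cohort_from_gaps(g1, g2, arm):
    """Build complete-case records whose analysis gaps are exactly (g1, g2)."""
    recs = []
    for i, (a, u, v) in enumerate(zip(arm, g1, g2)):
        t1 = 5.0 + 0.01 * i
        recs.append(
            make_record(f"s{i}", int(a), (t1, t1 + u, t1 + u + v), (1, 1, 1))
        )
    return Cohort(records=tuple(recs))


class TestRegressionFit:
    def test_noise_free_data_recovers_line_exactly(self, fast_mcmc, vague_prior):
        g1 = np.array([10.0, 20, 30, 40, 50, 60])
        g2 = 3.0 + 0.5 * g1
        cohort = cohort_from_gaps(g1, g2, np.zeros(6))
        fit = fit_gap_regression(cohort, 0, vague_prior, fast_mcmc)
        assert fit.slope == pytest.approx(0.5, abs=1e-3)
        assert fit.intercept == pytest.approx(3.0, abs=0.05)
        assert fit.residual_sd < 0.05
        # the analytic vague-prior posterior mean is the line exactly
        X = np.column_stack([np.ones_like(g1), g1])
        closed = posterior_mean_known_scale(X, g2, 1.0, PriorSpec.flat())
        assert np.allclose(closed, [3.0, 0.5], atol=1e-10)

    def test_vague_prior_posterior_mean_is_least_squares(self, rng):
        g1 = rng.uniform(10, 300, 5)
        g2 = 20 + 0.4 * g1 + rng.normal(0, 15, 5)
        X = np.column_stack([np.ones(5), g1])
        ls = np.linalg.lstsq(X, g2, rcond=None)[0]
        closed = posterior_mean_known_scale(X, g2, 12.0, PriorSpec.flat())
        assert np.allclose(closed, ls, atol=1e-6)

    def test_recovery_of_true_slope_large_n(self, vague_prior):
        p = SyntheticParams(
            n_arm0=2000, n_arm1=10, reg_slopes=(0.4, 0.4), seed=31
        )
        cohort, _ = generate_cohort(p)
        mcmc = MCMCSettings(chains=2, iterations=2000, burn_in=500, seed=8)
        fit = fit_gap_regression(cohort, 0, vague_prior, mcmc)
        row = fit.summary.table.loc["slope"]
        assert abs(row["mean"] - 0.4) < 3 * row["sd"]

    def test_insufficient_records_rejected(self, fast_mcmc, vague_prior):
        cohort = cohort_from_gaps([10.0, 20.0], [5.0, 6.0], [0, 0])
        with pytest.raises(GapsurvError, match="complete-case"):
            fit_gap_regression(cohort, 0, vague_prior, fast_mcmc)

    def test_zero_variance_first_gap_rejected(self, fast_mcmc, vague_prior):
        cohort = cohort_from_gaps(
            [10.0, 10.0, 10.0, 10.0], [5.0, 6.0, 7.0, 8.0], [0, 0, 0, 0]
        )
        with pytest.raises(GapsurvError, match="variance"):
            fit_gap_regression(cohort, 0, vague_prior, fast_mcmc)

    def test_log_scale_flag(self, default_cohort, fast_mcmc, vague_prior):
        cohort, _ = default_cohort
        fit = fit_gap_regression(cohort, 0, vague_prior, fast_mcmc,
                                 log_scale=True)
        df = gap_matrix(cohort.by_arm(0))
        ls = np.linalg.lstsq(
            np.column_stack([np.ones(len(df)), np.log(df["gap2"])]),
            np.log(df["gap3"]), rcond=None,
        )[0]
        assert abs(fit.slope - ls[1]) < 0.2


class TestArmDifference:
    def fit_pair(self, params, mcmc, prior):
        cohort, _ = generate_cohort(params)
        f0 = fit_gap_regression(cohort, 0, prior, mcmc)
        f1 = fit_gap_regression(cohort, 1, prior, mcmc)
        return f0, f1

    def test_identical_arms_centred_at_zero(self, vague_prior):
        # intercept well above the noise SD so the positivity redraw never
        # bends the conditional mean (the regression is then exactly linear)
        p = SyntheticParams(
            n_arm0=500, n_arm1=500, reg_slopes=(0.35, 0.35),
            reg_intercepts=(120.0, 120.0), noise_sd=20.0, seed=17,
        )
        mcmc = MCMCSettings(chains=2, iterations=3000, burn_in=1000, seed=9)
        f0, f1 = self.fit_pair(p, mcmc, vague_prior)
        diff = arm_effect_difference(f0, f1)
        assert abs(diff.mean) < 3 * diff.sd

    def test_true_slope_gap_recovered(self, vague_prior):
        p = SyntheticParams(
            n_arm0=800, n_arm1=800, reg_slopes=(0.3, 0.6), seed=23
        )
        mcmc = MCMCSettings(chains=2, iterations=2000, burn_in=500, seed=10)
        f0, f1 = self.fit_pair(p, mcmc, vague_prior)
        diff = arm_effect_difference(f0, f1)
        assert abs(diff.mean - 0.3) < 3 * diff.sd

    def test_tail_probabilities_normalise(self, default_cohort, fast_mcmc,
                                          vague_prior):
        cohort, _ = default_cohort
        f0 = fit_gap_regression(cohort, 0, vague_prior, fast_mcmc)
        f1 = fit_gap_regression(cohort, 1, vague_prior, fast_mcmc)
        diff = arm_effect_difference(f0, f1)
        assert diff.prob_positive + diff.prob_nonpositive == 1.0
        assert (diff.density["density"] >= 0).all()

    def test_antisymmetric_under_arm_swap(self, default_cohort, fast_mcmc,
                                          vague_prior):
        cohort, _ = default_cohort
        f0 = fit_gap_regression(cohort, 0, vague_prior, fast_mcmc)
        f1 = fit_gap_regression(cohort, 1, vague_prior, fast_mcmc)
        d01 = arm_effect_difference(f0, f1)
        d10 = arm_effect_difference(f1, f0)
        assert d01.mean == pytest.approx(-d10.mean, abs=1e-12)
        assert np.allclose(d01.draws, -d10.draws)

    def test_same_arm_fits_rejected(self, default_cohort, fast_mcmc, vague_prior):
        cohort, _ = default_cohort
        f0 = fit_gap_regression(cohort, 0, vague_prior, fast_mcmc)
        with pytest.raises(GapsurvError):
            arm_effect_difference(f0, f0)


class TestCombined:
    def test_additivity_on_synthetic_truth(self, vague_prior):
        # AFT arm effect 0.2 on the first gap, slope gap 0.3: the combined
        # signal should centre near 0.5
        p = SyntheticParams(
            n_arm0=1500, n_arm1=1500, beta1_arm=0.2,
            reg_slopes=(0.3, 0.6), seed=41,
        )
        cohort, _ = generate_cohort(p)
        mcmc = MCMCSettings(chains=2, iterations=2000, burn_in=500, seed=3)
        df = gap_matrix(cohort)
        aft = fit_aft_bayes(
            df["gap2"].to_numpy(), df["arm"].to_numpy(float),
            vague_prior, mcmc,
        )
        f0 = fit_gap_regression(cohort, 0, vague_prior, mcmc)
        f1 = fit_gap_regression(cohort, 1, vague_prior, mcmc)
        diff = arm_effect_difference(f0, f1)
        rep = combined_arm_inference(aft, diff)
        row = rep.table.loc["combined"]
        assert abs(row["mean"] - 0.5) < 3 * row["sd"]
        assert rep.table.loc["aft_arm_effect", "mean"] == pytest.approx(
            aft.beta, abs=1e-6
        )

    def test_reproducible_under_fixed_seeds(self, default_cohort, fast_mcmc,
                                            vague_prior):
        cohort, _ = default_cohort
        df = gap_matrix(cohort)

        def build():
            aft = fit_aft_bayes(
                df["gap2"].to_numpy(), df["arm"].to_numpy(float),
                vague_prior, fast_mcmc,
            )
            f0 = fit_gap_regression(cohort, 0, vague_prior, fast_mcmc)
            f1 = fit_gap_regression(cohort, 1, vague_prior, fast_mcmc)
            return combined_arm_inference(aft, arm_effect_difference(f0, f1))

        assert build().table.equals(build().table)


class TestPrediction:
    def test_noise_free_prediction_collapses(self, fast_mcmc, vague_prior):
        g1 = np.array([2.0, 6, 10, 14, 18, 22, 26, 30])
        g2 = 3.0 + 0.5 * g1
        cohort = cohort_from_gaps(g1, g2, np.zeros(8))
        fit = fit_gap_regression(cohort, 0, vague_prior, fast_mcmc)
        pred = predict_next_gap(10.0, fit)
        assert pred["mean"] == pytest.approx(8.0, abs=0.1)
        assert pred["interval"][1] - pred["interval"][0] < 0.5

    def test_monotone_in_g1_with_positive_slope(self, default_cohort, fast_mcmc,
                                                vague_prior):
        cohort, _ = default_cohort
        fit = fit_gap_regression(cohort, 1, vague_prior, fast_mcmc)
        assert (fit.draws.column("slope") > 0).mean() > 0.99
        means = [predict_next_gap(g, fit)["conditional_mean"]
                 for g in (50.0, 150.0, 400.0)]
        assert means[0] < means[1] < means[2]

    def test_nonpositive_g1_rejected(self, default_cohort, fast_mcmc, vague_prior):
        cohort, _ = default_cohort
        fit = fit_gap_regression(cohort, 0, vague_prior, fast_mcmc)
        with pytest.raises(GapsurvError):
            predict_next_gap(0.0, fit)
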