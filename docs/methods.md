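# Methods

## The model structure

Each patient contributes ordered event times `T_1 ≤ T_2 ≤ T_3` (days from
registration: loco-regional relapse, progression, death/last follow-up)
with per-event indicators.  The decomposition `G_1 = T_1`,
`G_j = T_j − T_{j−1}` turns the trajectory into gap times; the machinery
supports K ordered events, with three in all shipped presets.  Two
analysis gaps drive the dependent-gap inference: relapse→progression
(`G_2`) and progression→death (`G_3`).  The conventional endpoints map to
single event times — LRC to `T_1`, PFS to `T_2`, OS to `T_3`.

Gap analyses are **complete-case**: only patients with all three events
observed enter the AFT and dependency regressions (rows with missing
values are dropped at ingestion and counted).  The Cox and KM analyses
use all records with the usual right-censoring.

### AFT on gap times

`log G = μ + β·Arm + ε`, `ε ~ N(0, σ²)`.  Vague independent Gaussian
priors on (μ, β); a Gamma(0.001, 0.001) prior on the precision `1/σ²`.
Sampling is a two-block conjugate Gibbs scheme (multivariate-normal full
conditional for the coefficients, gamma for the precision).  Although the
error term can be formulated with unit variance, the reported third
parameter per model is the estimated residual SD σ on the log-time
scale — a fixed unit scale could not produce an estimated third row with
an HPD, so σ is estimated and the output metadata names the convention.

### Gap-dependency regression

`G₂ = β₀ₐ + β₁ₐ·G₁ + e` per arm, on raw gaps in days (a log-scale option
exists behind a flag).  "Auto-regression" means this lag-1 regression
across a patient's ordered gaps, not a time-series AR model.  A regression
of the first gap on the (identically zero) zeroth gap would be degenerate,
so only the second-gap-on-first-gap regression is fit.  The two arms are
fit independently; the slope-difference posterior is formed by
differencing draws aligned by index, which is valid because the arms'
chains are run on disjoint data from **independent sub-streams** (each fit
derives its own seed from the user seed; sharing a raw seed would
correlate the chains and collapse the spread of the difference).  The
combined arm signal adds AFT-arm-effect draws to slope-difference draws;
the two live on different scales (log-days vs dimensionless slope), which
is inherited from the strategy's definition and flagged in the report.

Posterior-predictive next-gap summaries draw
`β₀ + β₁·g₁ + N(0, σ)` per retained draw, propagating parameter and
residual uncertainty.

### Cox proportional hazards

Breslow-tied log partial likelihood (Efron by flag).  MLE by damped
Newton–Raphson on the analytic gradient/Hessian; Wald 95% CIs from the
inverse observed information; monotone likelihood is detected by
coefficient blow-up or collapse of the information matrix (SE > 10) and
reported as an error rather than a spurious estimate.

The Bayesian fit targets partial likelihood × independent Gaussian
priors.  The partial likelihood has no conjugate structure, so the
sampler is a component-wise random-walk Metropolis: proposal scales start
at 2.4× the Wald SEs and adapt every 50 iterations during burn-in toward
a 0.2–0.5 acceptance rate, then freeze so the retained chain is a valid
Markov chain.  The baseline hazard is left unmodelled (partial-likelihood
posterior); only covariate effects are reported.  Default chain layout:
4 chains × 10 000 iterations, 5 000 burn-in, thin 1; split-R̂ > 1.05
raises a warning.

**Prior parameterisation.** The vague prior is N(0, precision 0.001)
— i.e. variance 1000, the OpenBUGS convention.  A literal variance
reading (N(0, 0.001)) is selectable via
`PriorSpec(interpretation="variance")` but would pin every posterior mean
near zero; with the precision reading the vague-prior posterior means
coincide with the MLEs, which is the observable signature distinguishing
the two.  The default is the precision reading.

**PH supremum test.** The observed statistic is the per-covariate
supremum over time of the cumulative score process at the MLE; its null
distribution is approximated by Gaussian-multiplier resampling of the
score residuals including the correction for estimating β (the
Lin–Wei–Ying construction).  p = fraction of resampled suprema ≥
observed.  Calibration: empirical type-I error at nominal 0.05 measured
over 200 PH-true datasets in the test suite.

### Model metrics

* **AIC** = −2 log L + 2k for MLE fits.
* **DIC / pD**: pD = posterior-mean deviance − deviance at the posterior
  means; DIC = deviance-at-means + 2·pD.  The printed algebraic identity
  DIC = mean deviance + pD is verified to 1e−9 on every call.  An
  alternative pD formula sometimes printed in this literature
  (an expectation plus its own negative) is degenerate as written; the
  verbal definition above is implemented.  The deviance entering DIC is
  the same likelihood the sampler targets: the partial likelihood for Cox
  ("focused" DIC) and the full log-normal likelihood for the AFT.
* **HPD**: shortest window of ⌈prob·n⌉ sorted draws.  Valid for unimodal
  samples; a histogram-based multimodality screen warns otherwise.  Note
  the minimum-width selection leaves more Monte-Carlo noise in the
  endpoints than in the width.

## Synthetic cohort generator

Emulates the shape of a 74-patient two-arm trial (43 Arm-A / 31 Arm-B,
all three events observed) with the dependence structure the analysis
assumes:

| parameter | default | meaning |
|---|---|---|
| `mu1`, `beta1_arm`, `sigma1` | 5.3, 0.1, 0.8 | log-day intercept, arm effect, SD of the relapse→progression gap |
| `reg_intercepts`, `reg_slopes` | (30, 30), (0.30, 0.45) | per-arm linear link gap1 → gap2 (days) |
| `noise_sd` | 30 d | residual SD of the second gap |
| `t_relapse_scale` | 180 d | exponential scale of time to relapse |
| `censor_rate` | 0 | fraction administratively censored uniformly inside the trajectory |

Defaults put the AFT intercepts near 5.3 and 4.7 log-days, matching the
magnitudes such trials report.  The time-to-relapse distribution is not
part of the modelled structure, so a memoryless exponential is used and
documented as an assumption.  Second-gap positivity is enforced by
redrawing the noise term (≤1000 attempts) so the conditional mean stays
interpretable; when `noise_sd` is comparable to the intercept this
truncation bends the conditional mean slightly upward at small first
gaps, so calibration-sensitive checks (identical-arm centring, predictive
coverage) use parameters where the truncation never fires
(intercept ≫ noise SD).  Randomness uses numpy's PCG64 `default_rng` with
a single stream per cohort; identical parameters give bit-identical
cohorts across platforms.

What the generator does **not** emulate: covariate-dependent event rates
(age/gender are carried but null by default), covariate-dependent or
informative censoring, frailty, staggered recruitment, interval
censoring, or direct relapse→death transitions.  Passing tests therefore
demonstrate correctness of the estimators under the assumed structure,
not robustness to real-data violations of it.

## Numerical choices

* Partial-likelihood evaluation is O(n) after a one-off sort/tie-group,
  with a max-subtraction stabilised log-sum-exp over risk sets.
* Newton–Raphson uses step-halving; convergence requires gradient norm
  < 1e−9.
* Zero gaps between observed events are rejected at construction (log
  models are undefined there) rather than nudged by an epsilon.
* KM ties follow the standard convention: events precede censorings at
  the same time.  Estimation is delegated to lifelines; curves are
  exported as tidy CSV, and plotting is left to the caller.
* Age enters Cox models standardised (per-SD coefficient) by default;
  raw or binarised coding is available via the model spec.
* Draw alignment across independently fitted models truncates to the
  shorter draw count before element-wise combination.

## Problem sizes in shipped checks

The test suite uses n = 74 and n = 2000 cohorts for recovery checks,
200 datasets of n = 150 with 200 multiplier resamples for the supremum
test calibration, 1000 held-out subjects for predictive coverage, and
short two-chain samplers (1200–6000 iterations) chosen so the full suite
and the acceptance script each complete in well under a minute to a few
minutes on one CPU.

## Known limitations

* The combined arm signal mixes scales by construction (see above).
* The AFT likelihood is complete-case; censored-gap AFT is out of scope.
* No time-varying covariates, stratified baselines, frailty, competing
  risks, or interval censoring.
* The Bayesian Cox posterior conditions on the partial likelihood, not a
  full model with a baseline-hazard prior.
* HPD intervals assume unimodality (contiguous-window definition).
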