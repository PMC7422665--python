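# gapsurv

Gap-time survival analysis for ordered cancer-progression events.

In multi-event oncology trials each patient passes through ordered disease
states — loco-regional relapse, progression, death — and the conventional
endpoints (LRC, PFS, OS) analyse each event separately, discarding how the
durations *between* events relate.  `gapsurv` implements an integrated
strategy for two-arm trials that treats the gap times

```
G_1 = T_1,    G_j = T_j − T_{j−1}
```

as dependent quantities:

* **Log-normal AFT per gap** — `log G = μ + β·Arm + ε`, `ε ~ N(0, σ²)`,
  fit by a conjugate Gibbs sampler under vague Gaussian priors; `exp(β)`
  is the multiplicative arm effect on the gap duration.
* **Arm-stratified dependency regression** — `G₂ = β₀ₐ + β₁ₐ·G₁ + e`
  within each arm; the slope difference `β₁₁ − β₁₀` measures how treatment
  changes the dependence of the second duration on the first, and its
  draw-wise sum with the AFT arm effect gives a combined arm signal.
  The fitted regression also predicts the progression→death duration from
  an observed relapse→progression duration.
* **Cox proportional hazards per endpoint** —
  `λ(t) = λ₀(t)·exp(β₁·Arm + β₂·Age + β₃·Gender)` by Breslow partial
  likelihood (Newton–Raphson MLE) and by a component-wise random-walk
  Metropolis posterior, with DIC/pD model comparison and a
  Kolmogorov-type supremum test of the PH assumption.
* **Kaplan–Meier curves** per arm and endpoint, plus a synthetic two-arm
  trial generator (default: 43 vs 31 subjects) so every analysis is
  runnable without patient data.

It is aimed at biostatisticians analysing progression data from two-arm
trials, particularly when follow-up disruption makes the links between
successive events more informative than any single endpoint.

## Worked example

```python
from gapsurv import (SyntheticParams, generate_cohort, fit_gap_regression,
                     arm_effect_difference, predict_next_gap,
                     PriorSpec, MCMCSettings)

cohort, truth = generate_cohort(SyntheticParams(seed=13))
mcmc = MCMCSettings(chains=2, iterations=4000, burn_in=2000, seed=13)
fits = {a: fit_gap_regression(cohort, a, PriorSpec(), mcmc) for a in (0, 1)}
diff = arm_effect_difference(fits[0], fits[1])
pred = predict_next_gap(200.0, fits[1])
```

prints (via `python examples/gap_dependency.py`):

```
arm 0 (n=43): intercept   20.5, slope 0.310, residual SD 30.4
arm 1 (n=31): intercept   35.8, slope 0.452, residual SD 26.7

slope difference (arm1 - arm0): 0.142 (sd 0.030), 95% HPD (0.081, 0.198), P(diff > 0) = 1.000

after a 200-day relapse->progression gap in Arm-B, the predicted progression->death gap is 127 days (95% interval 72-180)
```

The per-arm slopes recover the generative values (0.30 and 0.45): each
extra day of relapse→progression time adds ~0.31 days (Arm-A) or ~0.45
days (Arm-B) of expected progression→death time, the posterior of the
slope difference sits near the true 0.15 and excludes zero, and the
predictive interval propagates both parameter and residual uncertainty.

The other scripts in `examples/` cover simulation, KM curves, Cox fits
with the PH supremum test, AFT fits per gap, and the full pipeline with
report tables (`examples/full_strategy.py`).  The same stages are exposed
as a CLI: `gapsurv simulate | km | cox | aft | depreg | run`.

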