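"""Conjugate Gibbs sampler for the normal linear model.

Backs both the log-normal AFT fit (response = log gap time, design =
[1, arm]) and the per-arm gap-dependency regression (response = second gap,
design = [1, first gap]).  The model is

    y = X b + e,   e ~ N(0, sigma^2 I)

with independent N(prior_mean, 1/tau0) priors on the coefficients and a
Gamma(shape, rate) prior on the residual precision 1/sigma^2.  Both full
conditionals are available in closed form, so the sampler is a plain
two-block Gibbs scheme: multivariate normal for b given sigma^2, gamma for
the precision given b.
"""

from __future__ import annotations

import numpy as np

from .core_data import GapsurvError
from .metrics import MCMCSettings, PosteriorDraws, PriorSpec

__all__ = [
    "posterior_mean_known_scale",
    "gibbs_linear",
]


def posterior_mean_known_scale(
    X: np.ndarray, y: np.ndarray, sigma: float, prior: PriorSpec
) -> np.ndarray:
    """Exact posterior mean of the coefficients when sigma is known.

    With prior precision tau0 -> 0 this reduces to the ordinary
    least-squares solution (X'X)^-1 X'y.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    tau0 = prior.precision
    prec = tau0 * np.eye(X.shape[1]) + X.T @ X / sigma**2
    rhs = X.T @ y / sigma**2 + tau0 * prior.mean * np.ones(X.shape[1])
    return np.linalg.solve(prec, rhs)


def _coef_conditional(X, y, sigma2, prior):
    tau0 = prior.precision
    prec = tau0 * np.eye(X.shape[1]) + X.T @ X / sigma2
    cov = np.linalg.inv(prec)
    mean = cov @ (X.T @ y / sigma2 + tau0 * prior.mean * np.ones(X.shape[1]))
    return mean, cov


def gibbs_linear(
    X: np.ndarray,
    y: np.ndarray,
    prior: PriorSpec,
    mcmc: MCMCSettings,
    names: tuple[str, ...],
    fix_scale: float | None = None,
) -> PosteriorDraws:
    """Gibbs draws of the coefficients and (unless fixed) the residual SD.

    Returns a :class:`PosteriorDraws` whose columns are ``names`` followed
    by ``"scale"`` when the residual SD is sampled.  Chains start from the
    least-squares solution perturbed per chain, with per-chain seeds
    spawned from ``mcmc.seed`` so runs are reproducible.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if y.shape != (n,):
        raise GapsurvError(f"shape mismatch: X {X.shape}, y {y.shape}")
    if len(names) != p:
        raise GapsurvError("one name per design column required")
    if n <= p:
        raise GapsurvError(f"need more observations ({n}) than coefficients ({p})")
    if np.linalg.matrix_rank(X) < p:
        raise GapsurvError("design matrix is rank deficient")

    sample_scale = fix_scale is None
    if not sample_scale and fix_scale <= 0:
        raise GapsurvError("fix_scale must be positive")

    ls_coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ ls_coef
    s2_init = float(resid @ resid) / max(n - p, 1)
    s2_init = max(s2_init, 1e-12)

    out_names = tuple(names) + (("scale",) if sample_scale else ())
    kept = mcmc.kept
    draws = np.empty((mcmc.chains, kept, len(out_names)))

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    for c in range(mcmc.chains):
        rng = np.random.default_rng(seeds[c])
        b = ls_coef + rng.normal(scale=np.sqrt(s2_init) + 0.1, size=p) * 0.5
        sigma2 = fix_scale**2 if not sample_scale else s2_init * rng.uniform(0.5, 2.0)
        k = 0
        for it in range(mcmc.iterations):
            mean, cov = _coef_conditional(X, y, sigma2, prior)
            b = rng.multivariate_normal(mean, cov, method="cholesky")
            if sample_scale:
                r = y - X @ b
                shape = prior.gamma_shape + 0.5 * n
                rate = prior.gamma_rate + 0.5 * float(r @ r)
                sigma2 = 1.0 / rng.gamma(shape, 1.0 / rate)
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                if sample_scale:
                    draws[c, k] = np.append(b, np.sqrt(sigma2))
                else:
                    draws[c, k] = b
                k += 1
        assert k == kept

    return PosteriorDraws(names=out_names, draws=draws, seed=mcmc.seed)
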