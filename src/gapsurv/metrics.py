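"""Posterior containers and model-comparison metrics shared by all fitters.

Houses the MCMC draw container, AIC, DIC with its effective-parameter
penalty pD, highest-posterior-density intervals, and the posterior summary
used to build the report tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core_data import GapsurvError

__all__ = [
    "PriorSpec",
    "MCMCSettings",
    "PosteriorDraws",
    "FitSummary",
    "aic",
    "dic",
    "hpd_interval",
    "summarize",
]


@dataclass(frozen=True)
class PriorSpec:
    """Independent Gaussian prior on each regression coefficient.

    ``value`` is 0.001 by default and is read as a *precision* (variance
    1000), the OpenBUGS parameterisation of a vague normal prior; set
    ``interpretation="variance"`` to read it literally as a variance.
    ``value = 0`` with the precision reading gives a flat prior.
    The residual precision (where estimated) gets a Gamma(shape, rate)
    prior, vague by default.
    """

    mean: float = 0.0
    value: float = 0.001
    interpretation: str = "precision"
    gamma_shape: float = 0.001
    gamma_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.interpretation not in ("precision", "variance"):
            raise GapsurvError(
                f"prior interpretation must be 'precision' or 'variance', "
                f"got {self.interpretation!r}"
            )
        if self.value < 0:
            raise GapsurvError("prior value must be >= 0")

    @property
    def precision(self) -> float:
        if self.interpretation == "precision":
            return self.value
        if self.value == 0:
            raise GapsurvError("variance 0 prior is degenerate")
        return 1.0 / self.value

    @classmethod
    def flat(cls) -> "PriorSpec":
        return cls(value=0.0, interpretation="precision")


@dataclass(frozen=True)
class MCMCSettings:
    """Chain layout for the samplers.

    Defaults (4 chains x 10000 iterations, 5000 burn-in, thin 1) are sized
    for a final analysis; tests and quick looks pass smaller values.
    """

    chains: int = 4
    iterations: int = 10000
    burn_in: int = 5000
    thin: int = 1
    seed: int = 12345

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise GapsurvError("iterations must exceed burn_in")
        if self.chains < 1 or self.thin < 1:
            raise GapsurvError("chains and thin must be >= 1")

    @property
    def kept(self) -> int:
        return (self.iterations - self.burn_in + self.thin - 1) // self.thin


@dataclass(frozen=True)
class PosteriorDraws:
    """MCMC sample matrix with chain metadata.

    ``draws`` has shape (chains, kept_iterations, parameters); draws are
    post burn-in and post thinning.  ``acceptance`` maps parameter name to
    post-burn-in Metropolis acceptance rate where applicable.
    """

    names: tuple[str, ...]
    draws: np.ndarray
    seed: int | None = None
    acceptance: dict[str, float] | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.draws, dtype=float)
        if d.ndim != 3:
            raise GapsurvError(
                f"draws must be (chains, iterations, params), got shape {d.shape}"
            )
        if d.shape[2] != len(self.names):
            raise GapsurvError("parameter-name count does not match draws")
        if not np.all(np.isfinite(d)):
            raise GapsurvError("non-finite posterior draws")
        object.__setattr__(self, "draws", d)
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def flat(self) -> np.ndarray:
        """All chains concatenated: shape (total_draws, parameters)."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def column(self, name: str) -> np.ndarray:
        return self.flat()[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.flat(), columns=list(self.names))
        df.insert(
            0, "chain",
            np.repeat(np.arange(self.n_chains), self.draws.shape[1]),
        )
        return df

    def to_csv(self, path) -> None:
        """Export one column per parameter for external diagnostics."""
        self.to_frame().to_csv(path, index=False)

    def rhat(self) -> dict[str, float]:
        """Split-R-hat per parameter (via arviz); needs >= 2 chains."""
        import arviz as az

        if self.n_chains < 2:
            raise GapsurvError("R-hat needs at least 2 chains")
        ds = az.convert_to_dataset(
            {n: self.draws[:, :, i] for i, n in enumerate(self.names)}
        )
        r = az.rhat(ds)
        return {n: float(r[n].values) for n in self.names}

    def ess(self) -> dict[str, float]:
        """Bulk effective sample size per parameter (via arviz)."""
        import arviz as az

        ds = az.convert_to_dataset(
            {n: self.draws[:, :, i] for i, n in enumerate(self.names)}
        )
        e = az.ess(ds)
        return {n: float(e[n].values) for n in self.names}


def derive_seed(seed: int, *key: int) -> int:
    """Stable sub-stream seed for a (seed, context) pair, below 2^31.

    Fits that are later combined draw-wise (per-arm regressions, the AFT
    fit) must not share a raw seed, or their chains would be correlated
    and differences/sums of aligned draws would have the wrong spread.
    """
    return int(np.random.SeedSequence([int(seed), *key]).generate_state(1)[0] >> 1)


def aic(loglik_at_mle: float, k: int) -> float:
    """Akaike information criterion: -2 log L + 2k."""
    if k < 0:
        raise GapsurvError("k must be >= 0")
    return -2.0 * loglik_at_mle + 2.0 * k


def dic(deviance_draws: Sequence[float], deviance_at_mean: float) -> tuple[float, float]:
    """Deviance information criterion and effective parameter count.

    pD is the posterior mean deviance minus the deviance at the posterior
    means; DIC = deviance_at_mean + 2 pD = mean deviance + pD.  The two
    algebraic forms are computed independently and required to agree to
    1e-9 as a guard against unit mistakes in the deviance inputs.
    """
    dev = np.asarray(deviance_draws, dtype=float)
    if dev.size == 0:
        raise GapsurvError("dic needs at least one deviance draw")
    if not (np.all(np.isfinite(dev)) and math.isfinite(deviance_at_mean)):
        raise GapsurvError("non-finite deviance")
    mean_dev = float(dev.mean())
    p_d = mean_dev - deviance_at_mean
    dic_value = deviance_at_mean + 2.0 * p_d
    alt = mean_dev + p_d
    if abs(dic_value - alt) > 1e-9 * max(1.0, abs(dic_value)):
        raise GapsurvError("DIC identity violated")  # pragma: no cover
    return dic_value, p_d


def hpd_interval(draws: Sequence[float], prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``prob`` posterior mass.

    Implements the sorted-window definition: among all windows of
    ``ceil(prob * n)`` consecutive order statistics, the narrowest.  Valid
    for unimodal posteriors; an apparent multimodal sample triggers a
    warning but still returns the shortest window.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n < 20:
        raise GapsurvError(f"hpd_interval needs >= 20 draws, got {n}")
    if not 0.0 < prob < 1.0:
        raise GapsurvError("prob must be in (0, 1)")
    m = int(math.ceil(prob * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    if _looks_multimodal(x):
        warnings.warn(
            "sample looks multimodal; contiguous HPD interval may be "
            "misleading",
            stacklevel=2,
        )
    return float(x[i]), float(x[i + m - 1])


def _looks_multimodal(sorted_draws: np.ndarray) -> bool:
    # cheap screen: smoothed histogram with more than one well-separated peak
    x = sorted_draws
    if x[-1] - x[0] <= 0:
        return False
    h, _ = np.histogram(x, bins=20)
    kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    s = np.convolve(h, kernel / kernel.sum(), mode="same")
    peaks = [
        i
        for i in range(1, len(s) - 1)
        if s[i] > s[i - 1] and s[i] >= s[i + 1] and s[i] > 0.3 * s.max()
    ]
    # multimodal only if two substantial peaks are separated by a deep valley
    for a, b in zip(peaks, peaks[1:]):
        valley = s[a:b + 1].min()
        if valley < 0.5 * min(s[a], s[b]):
            return True
    return False


@dataclass(frozen=True)
class FitSummary:
    """Per-parameter posterior summary plus model-level criteria.

    ``table`` is indexed by parameter with columns mean, sd, ci_lower,
    ci_upper (equal-tailed 95%), hpd_lower, hpd_upper.  ``dic`` and ``p_d``
    are present when a deviance function was supplied; ``aic`` when the fit
    has a maximum-likelihood counterpart.
    """

    table: pd.DataFrame
    dic: float | None = None
    p_d: float | None = None
    aic: float | None = None
    rhat: dict[str, float] | None = None
    metadata: dict = field(default_factory=dict)


def summarize(
    draws: PosteriorDraws,
    deviance_fn: Callable[[np.ndarray], float] | None = None,
    prob: float = 0.95,
    metadata: dict | None = None,
) -> FitSummary:
    """Deterministic posterior summary of a draw matrix.

    ``deviance_fn`` maps one parameter vector to its deviance (-2 log
    likelihood); when given, DIC and pD are computed from the per-draw
    deviances and the deviance at the posterior means.  Split-R-hat is
    reported and a warning raised above 1.05.
    """
    flat = draws.flat()
    if flat.size == 0:
        raise GapsurvError("empty draws")
    alpha = (1.0 - prob) / 2.0
    rows = {}
    for i, name in enumerate(draws.names):
        col = flat[:, i]
        lo, hi = np.quantile(col, [alpha, 1.0 - alpha])
        if col.size >= 20:
            h_lo, h_hi = hpd_interval(col, prob)
        else:  # tiny chains: fall back to the equal-tailed interval
            h_lo, h_hi = float(lo), float(hi)
        rows[name] = {
            "mean": float(col.mean()),
            "sd": float(col.std(ddof=1)) if col.size > 1 else 0.0,
            "ci_lower": float(lo),
            "ci_upper": float(hi),
            "hpd_lower": h_lo,
            "hpd_upper": h_hi,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "parameter"

    dic_value = p_d = None
    if deviance_fn is not None:
        devs = np.array([deviance_fn(theta) for theta in flat])
        dev_at_mean = float(deviance_fn(flat.mean(axis=0)))
        dic_value, p_d = dic(devs, dev_at_mean)

    rhat = None
    if draws.n_chains >= 2 and draws.draws.shape[1] >= 4:
        rhat = draws.rhat()
        worst = max(rhat.values())
        if worst > 1.05:
            warnings.warn(
                f"chains may not have converged: max split-R-hat {worst:.3f}",
                stacklevel=2,
            )
    return FitSummary(
        table=table, dic=dic_value, p_d=p_d, rhat=rhat,
        metadata=dict(metadata or {}),
    )
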