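"""Product-limit survival curves for the LRC / PFS / OS endpoints.

Estimation is delegated to lifelines' Kaplan-Meier fitter; this module
shapes the result into a tidy, plot-ready curve per arm.  Ties between an
event and a censoring at the same time follow the standard convention:
events are processed first, so the censored subject is still in the risk
set at that time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .core_data import Cohort, GapsurvError, extract_endpoint

__all__ = ["KMCurve", "km_estimate", "km_by_arm", "curves_to_frame"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class KMCurve:
    """A product-limit estimate as step-function data.

    ``times`` are the sorted distinct observed times (events and
    censorings); ``survival`` the estimate just after each time;
    ``at_risk`` and ``n_events`` the risk-set size and event count at each
    time.  ``ci_lower``/``ci_upper`` are Greenwood-based 95% bands.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.survival)
        if s.size and (np.any(np.diff(s) > 1e-12) or s.min() < -1e-12 or s.max() > 1 + 1e-12):
            raise GapsurvError("survival curve must be non-increasing in [0, 1]")

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); 1 before the first observed time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


def km_estimate(times, events, label: str = "") -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function.

    ``times`` must be positive; ``events`` are 1 for an observed event and
    0 for right censoring.  A censored-only input yields a curve flat at 1.
    """
    t = np.asarray(times, float)
    d = np.asarray(events, int)
    if t.size == 0:
        raise GapsurvError("km_estimate: empty input")
    if t.shape != d.shape:
        raise GapsurvError("times and events must have equal length")
    if np.any(t < 0):
        raise GapsurvError("negative time")

    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=d)
    # drop the synthetic t=0 anchor row lifelines prepends
    table = kmf.event_table[kmf.event_table.index > 0]
    tt = table.index.to_numpy(float)
    surv = np.array([kmf.predict(v) for v in tt], float)
    ci = kmf.confidence_interval_
    ci_lo = np.array([np.interp(v, ci.index.to_numpy(float), ci.iloc[:, 0].to_numpy()) for v in tt])
    ci_hi = np.array([np.interp(v, ci.index.to_numpy(float), ci.iloc[:, 1].to_numpy()) for v in tt])
    return KMCurve(
        times=tt,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(int),
        n_events=table["observed"].to_numpy(int),
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        label=label,
    )


def km_by_arm(cohort: Cohort, endpoint: str) -> dict[int, KMCurve]:
    """One Kaplan-Meier curve per treatment arm for the given endpoint.

    ``endpoint`` is ``lrc`` (time to relapse), ``pfs`` (time to
    progression) or ``os`` (time to death / last follow-up).  A single-arm
    cohort yields one curve and a logged warning.
    """
    times, events, covs = extract_endpoint(cohort, endpoint)
    arms = sorted(set(covs["arm"]))
    if len(arms) < 2:
        log.warning("km_by_arm: cohort has a single arm (%s)", arms)
    curves = {}
    for a in arms:
        mask = covs["arm"].to_numpy() == a
        name = cohort.arm_labels.get(a, str(a))
        curves[int(a)] = km_estimate(times[mask], events[mask], label=name)
    return curves


def curves_to_frame(curves: dict[int, KMCurve]) -> pd.DataFrame:
    """Tidy long-format export (time, survival, at_risk, ..., arm)."""
    frames = []
    for a, c in curves.items():
        df = c.to_frame()
        df["arm"] = a
        df["label"] = c.label
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
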