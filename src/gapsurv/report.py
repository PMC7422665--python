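"""End-to-end strategy orchestration and report-table rendering.

``run_strategy`` executes the full pipeline on a cohort (read from CSV or
simulated): complete-case subsetting for the gap analyses, Kaplan-Meier
curves per endpoint, Cox PH (MLE + Bayesian) per endpoint shaped like the
three-endpoint posterior table, log-normal AFT per analysis gap shaped
like the two-gap posterior table, per-arm gap regressions, the arm-effect
difference density, and the combined arm report.  Every artifact is
written with a manifest of package version, seeds and a config hash so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aft import fit_aft_bayes
from .core_data import (
    GapsurvError,
    complete_case_subset,
    gap_matrix,
    read_event_table,
    write_event_table,
)
from .cox import (
    CoxModelSpec,
    cox_data_from_cohort,
    fit_bayes,
    fit_mle,
    supremum_ph_test,
)
from .dependency import (
    arm_effect_difference,
    combined_arm_inference,
    fit_gap_regression,
)
from .kaplan_meier import curves_to_frame, km_by_arm
from .metrics import MCMCSettings, PriorSpec
from .synthetic import SyntheticParams, generate_cohort

__all__ = ["AnalysisConfig", "run_strategy", "render_tables"]

log = logging.getLogger(__name__)

ENDPOINT_ORDER = ("lrc", "pfs", "os")
GAP_LABELS = {1: "relapse_to_progression", 2: "progression_to_death"}


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything the end-to-end run needs, overridable from YAML/CLI."""

    input_path: str | None = None
    simulate: bool = True
    sim_params: SyntheticParams = field(default_factory=SyntheticParams)
    endpoints: tuple[str, ...] = ENDPOINT_ORDER
    gap_preset: tuple[int, int] = (1, 2)
    covariates: tuple[str, ...] = ("arm", "age", "gender")
    prior: PriorSpec = field(default_factory=PriorSpec)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    n_ph_resample: int = 1000
    output_dir: str = "gapsurv_out"

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "sim_params" in raw:
            sp = raw.pop("sim_params")
            for key in ("reg_intercepts", "reg_slopes"):
                if key in sp:
                    sp[key] = tuple(sp[key])
            kwargs["sim_params"] = SyntheticParams(**sp)
        if "prior" in raw:
            kwargs["prior"] = PriorSpec(**raw.pop("prior"))
        if "mcmc" in raw:
            kwargs["mcmc"] = MCMCSettings(**raw.pop("mcmc"))
        for key in ("endpoints", "gap_preset", "covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        kwargs.update(raw)
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise GapsurvError(f"stage {name!r} failed: {exc}") from exc
        log.info("stage %s: %.2fs", name, time.perf_counter() - t0)
        return out
    return wrap


def run_strategy(config: AnalysisConfig, write: bool = True) -> dict:
    """Run the full analysis; returns the in-memory bundle.

    The bundle contains one Cox table per endpoint (three by default), one
    AFT fit per analysis gap (two), one arm-effect difference density and
    one combined report, plus KM curves, the gap regressions and a
    manifest.  With ``write=True`` all artifacts land under
    ``config.output_dir``.
    """
    if config.simulate:
        cohort, truth = _stage("simulate")(generate_cohort, config.sim_params)
    else:
        if not config.input_path:
            raise GapsurvError("input_path required when simulate is false")
        cohort = _stage("ingest")(read_event_table, config.input_path)
        truth = None
    cc = complete_case_subset(cohort)
    log.info(
        "cohort n=%d (complete-case %d, dropped-at-ingest %d)",
        len(cohort), len(cc), cohort.n_dropped,
    )

    bundle: dict = {
        "cohort": cohort,
        "complete_case_n": len(cc),
        "truth": truth,
        "km": {},
        "cox": {},
        "aft": {},
        "regression": {},
    }

    for ep in config.endpoints:
        bundle["km"][ep] = _stage(f"km:{ep}")(km_by_arm, cohort, ep)

    for ep in config.endpoints:
        spec = CoxModelSpec(endpoint=ep, covariates=config.covariates)
        data = cox_data_from_cohort(cohort, spec)
        mle = _stage(f"cox_mle:{ep}")(fit_mle, data)
        bay = _stage(f"cox_bayes:{ep}")(fit_bayes, data, config.prior, config.mcmc)
        ph = _stage(f"ph_test:{ep}")(
            supremum_ph_test, mle, data, config.n_ph_resample, config.mcmc.seed
        )
        bundle["cox"][ep] = {"mle": mle, "bayes": bay, "ph_test": ph}

    df = gap_matrix(cc, config.gap_preset)
    for gi in config.gap_preset:
        gaps = df[f"gap{gi + 1}"].to_numpy(float)
        x = df["arm"].to_numpy(float)
        bundle["aft"][gi] = _stage(f"aft:gap{gi + 1}")(
            fit_aft_bayes, gaps, x, config.prior, config.mcmc
        )

    fits = {}
    for arm in (0, 1):
        fits[arm] = _stage(f"gapreg:arm{arm}")(
            fit_gap_regression, cohort, arm, config.prior, config.mcmc,
            config.gap_preset,
        )
    bundle["regression"] = fits
    diff = _stage("arm_diff")(arm_effect_difference, fits[0], fits[1])
    bundle["arm_difference"] = diff
    first_gap = config.gap_preset[0]
    bundle["combined"] = _stage("combined")(
        combined_arm_inference, bundle["aft"][first_gap], diff
    )

    bundle["manifest"] = {
        "gapsurv_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.mcmc.seed,
        "n_subjects": len(cohort),
        "n_complete_case": len(cc),
        "n_dropped": cohort.n_dropped,
        "prior": {"value": config.prior.value,
                  "interpretation": config.prior.interpretation},
    }

    if write:
        _write_bundle(bundle, config)
    return bundle


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1, default=_coerce))


def _coerce(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_bundle(bundle: dict, config: AnalysisConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_event_table(bundle["cohort"], out / "cohort.csv")
    if bundle["truth"] is not None:
        _json_dump(bundle["truth"], out / "truth.json")
    for ep, curves in bundle["km"].items():
        curves_to_frame(curves).to_csv(out / f"km_{ep}.csv", index=False)
    cox_tab, aft_tab = render_tables(bundle)
    cox_tab.to_csv(out / "cox_table.csv", index=False)
    aft_tab.to_csv(out / "aft_table.csv", index=False)
    for ep, fits in bundle["cox"].items():
        fits["bayes"].draws.to_csv(out / f"cox_draws_{ep}.csv")
        _json_dump(
            {
                "mle": dict(zip(fits["mle"].names, fits["mle"].coefficients)),
                "posterior_mean": dict(
                    zip(fits["bayes"].names, fits["bayes"].coefficients)
                ),
                "dic": fits["bayes"].summary.dic,
                "p_d": fits["bayes"].summary.p_d,
                "aic": fits["mle"].aic,
                "ph_supremum_p": fits["ph_test"],
            },
            out / f"cox_{ep}.json",
        )
    for gi, fit in bundle["aft"].items():
        fit.draws.to_csv(out / f"aft_draws_{GAP_LABELS.get(gi, gi)}.csv")
    bundle["arm_difference"].density.to_csv(
        out / "arm_difference_density.csv", index=False
    )
    _json_dump(
        {
            "mean": bundle["arm_difference"].mean,
            "sd": bundle["arm_difference"].sd,
            "hpd": list(bundle["arm_difference"].hpd),
            "prob_positive": bundle["arm_difference"].prob_positive,
        },
        out / "arm_difference.json",
    )
    bundle["combined"].table.to_csv(out / "combined_report.csv")
    _json_dump(bundle["manifest"], out / "manifest.json")


def _fmt(v: float) -> str:
    return f"{v:.2f}"


def render_tables(bundle: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shape the fits into the two posterior report tables.

    The Cox table has one block per endpoint with columns
    Response | Parameter | Posterior Mean (SD) | 95% HPD | DIC | pD | MLE;
    the AFT table mirrors it per gap with rows Intercept / Arm / Scale.
    Two-decimal formatting, SD in parentheses.
    """
    missing = [ep for ep in bundle.get("cox", {}) if "bayes" not in bundle["cox"][ep]]
    rows = []
    for ep, fits in bundle["cox"].items():
        if "bayes" not in fits or "mle" not in fits:
            raise GapsurvError(f"incomplete bundle: endpoint {ep!r}")
        bay, mle = fits["bayes"], fits["mle"]
        tab = bay.summary.table
        for i, name in enumerate(bay.names):
            r = tab.loc[name]
            rows.append(
                {
                    "Response": ep.upper() if i == 0 else "",
                    "Parameter": name.capitalize(),
                    "Posterior Mean (SD)": f"{_fmt(r['mean'])} ({_fmt(r['sd'])})",
                    "95% HPD": f"({_fmt(r['hpd_lower'])}, {_fmt(r['hpd_upper'])})",
                    "DIC": _fmt(bay.summary.dic) if i == 0 else "",
                    "pD": _fmt(bay.summary.p_d) if i == 0 else "",
                    "MLE": (
                        f"{_fmt(mle.coefficients[i])} "
                        f"({_fmt(mle.ci[i, 0])}, {_fmt(mle.ci[i, 1])})"
                    ),
                }
            )
    cox_table = pd.DataFrame(rows)

    rows = []
    param_label = {"intercept": "Intercept", "arm": "Arm", "scale": "Scale"}
    for gi, fit in bundle["aft"].items():
        tab = fit.summary.table
        for i, name in enumerate(fit.draws.names):
            r = tab.loc[name]
            rows.append(
                {
                    "Response": GAP_LABELS.get(gi, str(gi)) if i == 0 else "",
                    "Parameter": param_label.get(name, name),
                    "Posterior Mean (SD)": f"{_fmt(r['mean'])} ({_fmt(r['sd'])})",
                    "95% HPD": f"({_fmt(r['hpd_lower'])}, {_fmt(r['hpd_upper'])})",
                    "DIC": _fmt(fit.summary.dic) if i == 0 else "",
                    "pD": _fmt(fit.summary.p_d) if i == 0 else "",
                }
            )
    aft_table = pd.DataFrame(rows)
    return cox_table, aft_table
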