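"""Kaplan–Meier, log-rank and Cox proportional hazards analyses.

Each treatment arm is compared against the pooled placebo (all trials'
placebo arms concatenated).  Cox models adjust for sex (male vs female),
age (per 10 years) and BMI (per analysis-cohort SD), with Efron handling of
the heavy visit-month ties produced by clustered schedules.  Estimation is
delegated to lifelines; this module owns the covariate coding, pooled-
placebo construction, horizon truncation and the proportional-hazards
diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter, NelsonAalenFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "SurvivalEstimate",
    "CoxModelResult",
    "km_estimate",
    "logrank",
    "cox_fit",
    "ph_check",
    "pooled_placebo_frame",
    "truncate_at_horizon",
]


@dataclass
class SurvivalEstimate:
    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray


@dataclass
class CoxModelResult:
    """Hazard ratios with Wald 95% CIs and p-values per covariate."""

    hazard_ratios: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    p_values: dict[str, float]
    coefficients: dict[str, float]
    n_records: int
    n_events: int
    bmi_sd: float = np.nan  # cohort SD used for the per-SD BMI coding
    flagged: bool = False
    flag_reason: str = ""
    covariates: tuple[str, ...] = field(default_factory=tuple)


def km_estimate(durations, events, alpha: float = 0.05) -> SurvivalEstimate:
    """Product-limit survival estimate with log-log (exponential Greenwood)
    confidence bounds."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    if durations.size == 0:
        raise ValueError("km_estimate needs at least one record")
    kmf = KaplanMeierFitter(alpha=alpha)
    with np.errstate(over="ignore", invalid="ignore"):
        kmf.fit(durations, events)
        ci = kmf.confidence_interval_
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy()
    lo = ci.iloc[:, 0].to_numpy()
    hi = ci.iloc[:, 1].to_numpy()
    at_risk = kmf.event_table["at_risk"].reindex(times).to_numpy(dtype=float)
    return SurvivalEstimate(times=times, survival=surv, ci_lower=lo, ci_upper=hi, at_risk=at_risk)


def logrank(durations_a, events_a, durations_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, two-sided p)."""
    da, db = np.asarray(durations_a, float), np.asarray(durations_b, float)
    if da.size == 0 or db.size == 0:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(da, db, np.asarray(events_a, bool), np.asarray(events_b, bool))
    return float(res.test_statistic), float(res.p_value)


def pooled_placebo_frame(
    events: pd.DataFrame, participants: pd.DataFrame, treatment_trial: str
) -> pd.DataFrame:
    """Analysis frame for one treatment arm vs every trial's placebo arm.

    Returns the merged event + covariate table with a ``treated`` indicator;
    raises if either side is empty.
    """
    df = events.merge(participants, on="id", how="inner")
    treated = df.loc[(df["trial"] == treatment_trial) & (df["arm"] == "treatment")].copy()
    placebo = df.loc[df["arm"] == "placebo"].copy()
    if treated.empty:
        raise ValueError(f"no treated participants found for trial {treatment_trial!r}")
    if placebo.empty:
        raise ValueError("pooled placebo group is empty")
    treated["treated"] = 1
    placebo["treated"] = 0
    return pd.concat([treated, placebo], ignore_index=True)


def truncate_at_horizon(events: pd.DataFrame, horizon_months: float) -> pd.DataFrame:
    """Recode anything beyond the horizon as censored at the horizon."""
    out = events.copy()
    late = out["time_months"] > horizon_months
    out.loc[late, "event"] = False
    out.loc[late, "time_months"] = horizon_months
    return out


def cox_fit(
    frame: pd.DataFrame,
    covariates: tuple[str, ...] = ("treated", "sex", "age_years", "bmi"),
    duration_col: str = "time_months",
    event_col: str = "event",
) -> CoxModelResult:
    """Multivariate Cox PH fit with the study's covariate coding.

    ``sex`` is coded male=1 vs female=0, ``age_years`` as age/10, ``bmi``
    per SD of the analysis cohort at entry; any other column is used as is.
    Efron approximation for ties.  Monotone-likelihood / separation
    problems are reported via ``flagged`` rather than raised.
    """
    df = frame.copy()
    design = pd.DataFrame(index=df.index)
    names: list[str] = []
    bmi_sd = np.nan
    for cov in covariates:
        if cov == "sex":
            design["sex_male"] = (df["sex"].astype(str).str.upper() == "M").astype(float)
            names.append("sex_male")
        elif cov == "age_years":
            design["age_per_10y"] = df["age_years"].astype(float) / 10.0
            names.append("age_per_10y")
        elif cov == "bmi":
            bmi = df["bmi"].astype(float)
            bmi_sd = float(bmi.std(ddof=1))
            if not np.isfinite(bmi_sd) or bmi_sd == 0:
                raise ValueError("BMI has zero variance in the analysis cohort")
            design["bmi_per_sd"] = (bmi - bmi.mean()) / bmi_sd
            names.append("bmi_per_sd")
        else:
            design[cov] = df[cov].astype(float)
            names.append(cov)
    if design.isna().any().any():
        missing = design.columns[design.isna().any()].tolist()
        raise ValueError(f"covariates contain missing values: {missing}")
    design[duration_col] = df[duration_col].astype(float)
    design[event_col] = df[event_col].astype(bool)

    cph = CoxPHFitter()
    flagged, reason = False, ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(design, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        return CoxModelResult(
            hazard_ratios={}, ci_lower={}, ci_upper={}, p_values={}, coefficients={},
            n_records=len(design), n_events=int(design[event_col].sum()),
            bmi_sd=bmi_sd, flagged=True, flag_reason=f"convergence: {err}",
            covariates=tuple(names),
        )
    summ = cph.summary
    hr = summ["exp(coef)"].to_dict()
    lo = np.exp(summ["coef lower 95%"]).to_dict()
    hi = np.exp(summ["coef upper 95%"]).to_dict()
    pv = summ["p"].to_dict()
    coef = summ["coef"].to_dict()
    if np.any(np.abs(summ["coef"]) > 10):
        flagged, reason = True, "extreme_coefficient_possible_separation"
    return CoxModelResult(
        hazard_ratios=hr, ci_lower=lo, ci_upper=hi, p_values=pv, coefficients=coef,
        n_records=len(design), n_events=int(design[event_col].sum()),
        bmi_sd=bmi_sd, flagged=flagged, flag_reason=reason, covariates=tuple(names),
    )


def ph_check(
    durations, events, groups, eval_quantiles=(0.15, 0.85), n_eval: int = 20
) -> dict:
    """Log cumulative hazard curves per group and a parallelism summary.

    Under proportional hazards the two groups' log cumulative hazard curves
    differ by a constant vertical offset.  The curves are evaluated on a
    common grid of event-time quantiles; the summary reports the maximum
    absolute deviation of the offset from its median.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("ph_check expects exactly two groups")
    curves = {}
    for lab in labels:
        m = groups == lab
        naf = NelsonAalenFitter()
        naf.fit(durations[m], events[m])
        curves[lab] = naf.cumulative_hazard_

    ev_times = durations[events]
    if ev_times.size == 0:
        raise ValueError("no events; proportional hazards check undefined")
    grid = np.linspace(
        np.quantile(ev_times, eval_quantiles[0]), np.quantile(ev_times, eval_quantiles[1]), n_eval
    )

    def log_h(ch: pd.DataFrame, t: np.ndarray) -> np.ndarray:
        times = ch.index.to_numpy(dtype=float)
        vals = ch.iloc[:, 0].to_numpy()
        idx = np.searchsorted(times, t, side="right") - 1
        out = np.where(idx >= 0, vals[np.clip(idx, 0, None)], 0.0)
        return np.log(np.where(out > 0, out, np.nan))

    la = log_h(curves[labels[0]], grid)
    lb = log_h(curves[labels[1]], grid)
    offset = lb - la
    ok = np.isfinite(offset)
    if ok.sum() < 3:
        deviation = np.nan
    else:
        deviation = float(np.nanmax(np.abs(offset[ok] - np.nanmedian(offset[ok]))))
    return {
        "groups": tuple(labels.tolist()),
        "grid": grid,
        "log_cumhaz": {lab: log_h(curves[lab], grid) for lab in labels},
        "offset_deviation": deviation,
    }
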