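"""End-to-end orchestration: simulate → fit → endpoints → survival →
prediction → time-course.

Every stage is importable on its own; `run_pipeline` chains them on
in-memory tables and optionally writes each output as CSV with a
provenance header (config hash + seed), so reruns with the same
configuration are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .endpoints import EndpointSpec, HBA1C_THRESHOLD_MMOL_MOL, build_event_table, normalize_series
from .kinetics import CPeptideKinetics
from .prediction import PREDICTORS, build_outcome, fit_response_model
from .secretion import FitOptions, fit_beta_cell_model
from .survival import cox_fit, km_estimate, logrank, pooled_placebo_frame, truncate_at_horizon
from .synthetic import SimConfig, simulate_cohort
from .timecourse import compare_timecourse, pool_by_outcome

logger = logging.getLogger("betasens")

__all__ = ["PipelineConfig", "fit_cohort", "run_pipeline", "baseline_features"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    out_dir: str | Path | None = None
    sim: SimConfig | None = None  # simulate when set, otherwise read paths
    participants_path: str | Path | None = None
    visits_path: str | Path | None = None
    mmtt_path: str | Path | None = None
    kinetics_mode: str = "population"  # population | fixed
    fixed_kinetics: CPeptideKinetics | None = None
    nbgs_loss_threshold: float = 0.10
    naucc_loss_threshold: float = 0.10
    hba1c_threshold: float = HBA1C_THRESHOLD_MMOL_MOL
    horizon_months: float | None = 24.0
    trial_labels: dict[str, str] = field(default_factory=dict)
    fit_options: FitOptions = field(default_factory=FitOptions)
    seed: int = 0
    log_level: str = "INFO"
    write: bool = True

    def hash(self) -> str:
        payload = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("out_dir", "write", "fixed_kinetics", "fit_options")
        }
        return bio.config_hash(payload)


def fit_cohort(
    mmtt: pd.DataFrame,
    participants: pd.DataFrame,
    kinetics_mode: str = "population",
    fixed_kinetics: CPeptideKinetics | None = None,
    fit_options: FitOptions | None = None,
) -> pd.DataFrame:
    """Fit the beta cell model to every MMTT in a cohort.

    Returns one row per (id, month) with every scalar model output plus the
    QC flag.  Kinetics are per-participant population formulas unless a
    fixed set is supplied.
    """
    if kinetics_mode not in ("population", "fixed"):
        raise ValueError("kinetics_mode must be 'population' or 'fixed'")
    if kinetics_mode == "fixed" and fixed_kinetics is None:
        raise ValueError("kinetics_mode='fixed' requires fixed_kinetics")
    pmeta = participants.set_index("id")
    base_opt = fit_options or FitOptions()
    rows = []
    for (pid, month), grp in mmtt.groupby(["id", "month"], sort=True):
        meta = pmeta.loc[pid]
        if kinetics_mode == "population":
            kin = CPeptideKinetics.population(
                age_years=float(meta["age_years"]), bsa_m2=float(meta["bsa"]),
                sex=str(meta["sex"]),
            )
        else:
            kin = fixed_kinetics
        opt = FitOptions(**{**base_opt.__dict__, "bsa_m2": float(meta["bsa"])})
        grp = grp.sort_values("minute")
        fit = fit_beta_cell_model(
            grp["minute"].to_numpy(), grp["glucose_mmol_l"].to_numpy(),
            grp["cpeptide_nmol_l"].to_numpy(), kin, opt,
        )
        rows.append(
            dict(id=pid, month=month, beta_gs=fit.beta_gs,
                 rate_sensitivity=fit.rate_sensitivity,
                 potentiation_ratio=fit.potentiation_ratio,
                 basal_isr=fit.basal_isr, total_output=fit.total_output,
                 auc_cp=fit.auc_cp, incremental_auc_cp=fit.incremental_auc_cp,
                 fit_r2=fit.fit_r2, flagged=fit.flagged, flag_reason=fit.flag_reason)
        )
    return pd.DataFrame(rows)


def baseline_features(
    fits: pd.DataFrame, visits: pd.DataFrame, participants: pd.DataFrame
) -> pd.DataFrame:
    """Baseline (month 0) predictor table for the HbA1c response model."""
    base_fit = fits.loc[
        (fits["month"] == 0.0) & (~fits["flagged"].astype(bool)) & (fits["beta_gs"] > 0)
    ]
    base_visit = visits.loc[visits["month"] == 0.0]
    df = (
        base_fit[["id", "beta_gs"]]
        .merge(base_visit[["id", "hba1c_mmol_mol", "insulin_dose_u_kg_day"]], on="id")
        .merge(participants[["id", "age_years"]], on="id")
    )
    df["log_beta_gs"] = np.log(df["beta_gs"])
    return df


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the output bundle.

    The bundle maps stage names to DataFrames / result objects.  With
    ``config.write`` and ``config.out_dir`` set, each table is also written
    as CSV with the seed and config hash in a comment header.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    cfg_hash = config.hash()

    if config.sim is not None:
        cohort = simulate_cohort(config.sim)
        participants, visits, mmtt = cohort.participants, cohort.visits, cohort.mmtt
        truth = cohort.truth
    else:
        if not (config.participants_path and config.visits_path and config.mmtt_path):
            raise ValueError("either sim or all three input paths must be set")
        tables = bio.read_tables(
            {
                "participants": config.participants_path,
                "visits": config.visits_path,
                "mmtt": config.mmtt_path,
            }
        )
        participants, visits, mmtt = tables["participants"], tables["visits"], tables["mmtt"]
        truth = None

    logger.info("fitting %d MMTTs", mmtt.groupby(["id", "month"]).ngroups)
    fits = fit_cohort(
        mmtt, participants, config.kinetics_mode, config.fixed_kinetics, config.fit_options
    )
    series, excluded = normalize_series(fits, visits)

    event_tables = {
        "nbgs_loss": build_event_table(series, EndpointSpec("nbgs_loss", config.nbgs_loss_threshold)),
        "hba1c_threshold": build_event_table(
            series, EndpointSpec("hba1c_threshold", config.hba1c_threshold)
        ),
        "naucc_loss": build_event_table(
            series, EndpointSpec("naucc_loss", config.naucc_loss_threshold)
        ),
    }
    events = pd.concat(event_tables.values(), ignore_index=True)

    # survival: each trial's treatment arm vs pooled placebo
    km_rows, cox_rows = [], []
    trials = sorted(participants["trial"].unique())
    for endpoint, etab in event_tables.items():
        if config.horizon_months is not None:
            etab = truncate_at_horizon(etab, config.horizon_months)
        for trial in trials:
            try:
                frame = pooled_placebo_frame(etab, participants, trial)
            except ValueError:
                continue
            tr = frame.loc[frame["treated"] == 1]
            pl = frame.loc[frame["treated"] == 0]
            stat, p = logrank(
                tr["time_months"], tr["event"], pl["time_months"], pl["event"]
            )
            for label, sub in (("treatment", tr), ("pooled_placebo", pl)):
                est = km_estimate(sub["time_months"], sub["event"])
                for t, s, lo, hi, ar in zip(
                    est.times, est.survival, est.ci_lower, est.ci_upper, est.at_risk
                ):
                    km_rows.append(
                        dict(endpoint=endpoint, trial=trial, group=label, time_months=t,
                             survival=s, ci_lower=lo, ci_upper=hi, at_risk=ar,
                             logrank_stat=stat, logrank_p=p)
                    )
            cres = cox_fit(frame)
            for cov in cres.covariates:
                cox_rows.append(
                    dict(endpoint=endpoint, trial=trial, covariate=cov,
                         hr=cres.hazard_ratios.get(cov, np.nan),
                         ci_lower=cres.ci_lower.get(cov, np.nan),
                         ci_upper=cres.ci_upper.get(cov, np.nan),
                         p=cres.p_values.get(cov, np.nan),
                         n_records=cres.n_records, n_events=cres.n_events,
                         bmi_sd=cres.bmi_sd, flagged=cres.flagged)
                )
    km = pd.DataFrame(km_rows)
    cox = pd.DataFrame(cox_rows)

    # baseline prediction of 1-year HbA1c response
    outcome = build_outcome(visits)
    feats = baseline_features(fits, visits, participants).merge(outcome[["id", "outcome"]], on="id")
    response = None
    response_table = pd.DataFrame()
    if len(feats) >= 10 and feats["outcome"].nunique() == 2:
        response = fit_response_model(feats[list(PREDICTORS)], feats["outcome"])
        response_table = pd.DataFrame(
            [
                dict(predictor=k, odds_ratio_per_sd=response.odds_ratios[k],
                     ci_lower=response.ci_lower[k], ci_upper=response.ci_upper[k],
                     univariate_or=response.univariate_odds_ratios[k],
                     roc_auc=response.roc_auc, n=response.n,
                     prevalence=response.prevalence)
                for k in response.odds_ratios
            ]
        )

    # positive-vs-negative trial time course
    timecourse = None
    if config.trial_labels:
        pos, neg = pool_by_outcome(participants, config.trial_labels)
        timecourse = compare_timecourse(series, pos, neg)

    bundle = {
        "participants": participants, "visits": visits, "mmtt": mmtt, "truth": truth,
        "fits": fits, "series": series, "excluded": excluded, "events": events,
        "km": km, "cox": cox, "outcome": outcome, "response": response,
        "response_table": response_table, "timecourse": timecourse,
        "config_hash": cfg_hash,
    }

    if config.write and config.out_dir is not None:
        out = Path(config.out_dir)
        for name in ("participants", "visits", "mmtt", "fits", "events", "km", "cox"):
            bio.write_table(bundle[name], out / f"{name}.csv", config.seed, cfg_hash)
        if truth is not None:
            bio.write_table(truth, out / "ground_truth.csv", config.seed, cfg_hash)
        if not response_table.empty:
            bio.write_table(response_table, out / "response_model.csv", config.seed, cfg_hash)
            bio.write_table(response.roc_points, out / "roc.csv", config.seed, cfg_hash)
        if timecourse is not None:
            bio.write_table(timecourse, out / "timecourse.csv", config.seed, cfg_hash)
    return bundle
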