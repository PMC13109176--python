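"""Synthetic stage 3 type 1 diabetes trial cohorts with known ground truth.

Every downstream stage (model fitting, endpoints, survival, prediction,
time-course comparison) is exercised against cohorts produced here, because
the real trial tables live in access-restricted repositories.  The generator
emulates the structure of those trials:

* participants enrolled at clinical (stage 3) onset, in children /
  adolescent / adult age strata, randomized to a treatment or placebo arm
  drawn from identical baseline distributions;
* true beta cell glucose sensitivity (βGS) declining exponentially after
  onset, faster in younger strata, with a multiplicative treatment effect on
  the decline rate while the drug's effect window is active;
* 2 h MMTTs at scheduled visits: a parametric glucose excursion and a
  C-peptide series obtained by forward-convolving the beta cell model's
  secretion rate with the two-exponential C-peptide kinetics, plus
  multiplicative assay noise;
* HbA1c falling with better beta cell function and insulin dose rising as it
  is lost;
* a small fraction of deliberately discordant glucose/C-peptide tests for
  quality-control testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinetics import CPeptideKinetics
from .secretion import _convolve_to_obs, _positive_glucose_rate

__all__ = [
    "TrialSpec",
    "SimConfig",
    "VisitTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "forward_mmtt",
    "inject_discordant",
    "true_nbgs",
]

_STRATA = ("children", "adolescents", "adults")
#: true βGS decline rates per year after stage 3 onset, by age stratum
_DECLINE_PER_YEAR = {"children": 0.65, "adolescents": 0.50, "adults": 0.32}
_AGE_RANGES = {"children": (3.5, 11.9), "adolescents": (12.0, 17.9), "adults": (18.0, 45.0)}
_BMI = {"children": (17.0, 2.0), "adolescents": (21.0, 3.0), "adults": (25.0, 4.0)}
_BSA = {"children": (1.10, 0.15), "adolescents": (1.60, 0.15), "adults": (1.85, 0.20)}


@dataclass(frozen=True)
class TrialSpec:
    """One trial: a multiplicative effect on the βGS decline rate that is
    active between onset and offset (months from randomization).  An effect
    of 1.0 is a null drug; 0.5 halves the decline rate while active."""

    name: str
    treatment_effect: float = 1.0
    effect_onset_months: float = 0.0
    effect_offset_months: float = 1e9


@dataclass(frozen=True)
class SimConfig:
    n_per_arm: int = 30
    trials: tuple[TrialSpec, ...] = (TrialSpec("drug", 0.5, 0.0, 12.0),)
    age_mix: tuple[float, float, float] = (0.22, 0.40, 0.38)
    visit_months: tuple[float, ...] = (0.0, 3.0, 6.0, 12.0, 18.0, 24.0)
    mmtt_minutes: tuple[float, ...] = (0.0, 15.0, 30.0, 60.0, 90.0, 120.0)
    cpeptide_cv: float = 0.05
    glucose_cv: float = 0.02
    discordant_rate: float = 0.037
    visit_jitter_months: float = 0.4
    dropout_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if len(self.trials) == 0:
            raise ValueError("trials must be non-empty")
        for t in self.trials:
            if t.treatment_effect < 0:
                raise ValueError("trials: treatment_effect must be >= 0")
            if t.effect_offset_months < t.effect_onset_months:
                raise ValueError("trials: effect_offset_months must be >= effect_onset_months")
        if len(self.age_mix) != 3 or abs(sum(self.age_mix) - 1.0) > 1e-9 or min(self.age_mix) < 0:
            raise ValueError("age_mix proportions must be nonnegative and sum to 1")
        vm = np.asarray(self.visit_months, dtype=float)
        if vm[0] != 0.0 or np.any(np.diff(vm) <= 0):
            raise ValueError("visit_months must be strictly increasing and start at 0")
        mm = np.asarray(self.mmtt_minutes, dtype=float)
        if mm.size < 4 or np.any(np.diff(mm) <= 0):
            raise ValueError("mmtt_minutes must be >= 4 strictly increasing values")
        if not 0.0 <= self.discordant_rate <= 0.2:
            raise ValueError("discordant_rate must be in [0, 0.2]")
        if self.cpeptide_cv < 0 or self.glucose_cv < 0:
            raise ValueError("noise: assay CVs must be >= 0")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")


@dataclass
class VisitTruth:
    """Ground-truth beta cell state at one visit, enough to forward-simulate
    the MMTT."""

    beta_gs: float  # pmol min⁻¹ m⁻² per mmol/l
    rate_sensitivity: float  # pmol m⁻² per mmol/l
    potentiation_slope: float  # p(t) = 1 + slope*(t - T/2)/T, dimensionless
    basal_isr: float  # pmol min⁻¹ m⁻²
    bsa_m2: float
    glucose_peak_min: float = 75.0

    @property
    def potentiation_ratio(self) -> float:
        s = self.potentiation_slope
        return (1.0 + s / 2.0) / (1.0 - s / 2.0)


@dataclass
class SimulatedCohort:
    participants: pd.DataFrame
    visits: pd.DataFrame
    mmtt: pd.DataFrame
    truth: pd.DataFrame
    discordant_labels: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)


def true_nbgs(months, decline_per_year, treatment_effect=1.0, onset=0.0, offset=1e9):
    """Closed-form normalized βGS trajectory of the generator.

    The decline rate is multiplied by ``treatment_effect`` during the effect
    window, so the cumulative log-loss at month m is the rate-weighted time
    ``(m - active) + effect * active`` with ``active`` the overlap of (0, m]
    and the window.  Exposed so tests can check trajectories in closed form.
    """
    m = np.asarray(months, dtype=float)
    active = np.clip(np.minimum(m, offset) - onset, 0.0, None)
    equiv_months = (m - active) + treatment_effect * active
    return np.exp(-decline_per_year * equiv_months / 12.0)


# ---------------------------------------------------------------------------


#: glucose threshold anchoring the dose-response (mmol/l): secretion above
#: basal is proportional to glucose excess over this level
GLUCOSE_THRESHOLD = 4.0


def _fasting_glucose(beta_gs: float) -> float:
    """Fasting glucose rises as glucose sensitivity is lost (mmol/l).

    The map is chosen so that basal secretion βGS*(G_fast - threshold) is
    approximately preserved while βGS declines: prevailing hyperglycaemia
    drives the remaining beta cells harder, which is exactly why C-peptide
    output (AUC_Cp) is a lagging indicator of function loss.
    """
    return float(np.clip(GLUCOSE_THRESHOLD + 70.0 / max(beta_gs, 1e-3), 4.5, 15.0))


def _glucose_excursion(beta_gs: float) -> float:
    """Meal glucose excursion (mmol/l), growing as βGS falls so that the
    meal-stimulated secretion increment is also largely glycaemia-compensated."""
    return float(np.clip(157.5 / max(beta_gs, 1e-3), 3.0, 12.0))


def _hba1c_mean(beta_gs: float) -> float:
    """Logistic-shaped inverse map from true βGS to mean HbA1c (mmol/mol)."""
    return 44.0 + 26.0 / (1.0 + np.exp((beta_gs - 12.0) / 5.0))


def _insulin_dose_mean(beta_gs: float) -> float:
    return 0.25 + 0.45 / (1.0 + beta_gs / 8.0)


def forward_mmtt(
    truth: VisitTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Forward-simulate one MMTT from ground-truth beta cell parameters.

    The glucose curve is parametric (fasting level rising as βGS falls, a
    peak near 60–90 min, partial return by 2 h).  The secretion rate follows
    the beta cell model — linear dose–response of slope βGS anchored at the
    basal rate, an affine mean-1 potentiation factor, and a rate-of-change
    component computed, like the downstream fit, from central differences on
    the sampling grid — and is convolved with the two-exponential C-peptide
    impulse response assuming pre-test steady state.  Multiplicative assay
    noise is applied last.

    Returns a frame with columns minute, glucose_mmol_l, cpeptide_nmol_l.
    """
    minutes = np.asarray(config.mmtt_minutes, dtype=float)
    if np.any(np.diff(minutes) <= 0):
        raise ValueError("mmtt_minutes must be strictly increasing")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    g0 = _fasting_glucose(truth.beta_gs)
    dg = _glucose_excursion(truth.beta_gs)
    tp = truth.glucose_peak_min
    shape = (minutes / tp) ** 2 * np.exp(2.0 * (1.0 - minutes / tp))
    g_nodes = g0 + dg * shape

    t_end = minutes[-1]
    t_fine = np.arange(minutes[0], t_end + 1e-9, 1.0)
    g_fine = np.interp(t_fine, minutes, g_nodes)
    r_fine = np.interp(t_fine, minutes, _positive_glucose_rate(minutes, g_nodes))

    duration = t_end - minutes[0]
    p_fine = 1.0 + truth.potentiation_slope * (t_fine - minutes[0] - duration / 2.0) / duration
    f_fine = np.maximum(truth.basal_isr + truth.beta_gs * (g_fine - g0), 0.0)
    isr_fine = p_fine * f_fine + truth.rate_sensitivity * r_fine

    kin = CPeptideKinetics.population(age_years=20.0, bsa_m2=truth.bsa_m2)
    h_fine = kin.a1 * np.exp(-kin.lam1 * t_fine) + kin.a2 * np.exp(-kin.lam2 * t_fine)
    tail = kin.tail_area(t_fine)
    obs_idx = np.searchsorted(t_fine, minutes - 1e-9)
    cp = _convolve_to_obs(isr_fine, h_fine, kin, 1.0, obs_idx, tail) * truth.bsa_m2

    if config.glucose_cv > 0:
        g_nodes = g_nodes * (1.0 + config.glucose_cv * rng.standard_normal(minutes.size))
    if config.cpeptide_cv > 0:
        cp = cp * (1.0 + config.cpeptide_cv * rng.standard_normal(minutes.size))
    g_nodes = np.maximum(g_nodes, 0.5)
    cp = np.maximum(cp, 1e-3)

    return pd.DataFrame(
        {"minute": minutes, "glucose_mmol_l": g_nodes, "cpeptide_nmol_l": cp}
    )


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full multi-trial cohort with ground truth.

    Reproducible: the same config (including seed) yields byte-identical
    tables.  Placebo and treated arms are drawn from the same baseline
    distributions; only the decline rate differs while a drug's effect
    window is active.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    participants, visits, mmtt, truth = [], [], [], []
    for ti, trial in enumerate(config.trials):
        for arm in ("treatment", "placebo"):
            effect = trial.treatment_effect if arm == "treatment" else 1.0
            for i in range(config.n_per_arm):
                pid = f"{trial.name}-{arm[:1]}{i:04d}"
                stratum = _STRATA[rng.choice(3, p=np.asarray(config.age_mix))]
                lo, hi = _AGE_RANGES[stratum]
                age = rng.uniform(lo, hi)
                sex = "M" if rng.random() < 0.5 else "F"
                bmi = float(np.clip(rng.normal(*_BMI[stratum]), 13.0, 45.0))
                bsa = float(np.clip(rng.normal(*_BSA[stratum]), 0.6, 2.6))

                beta0 = float(rng.lognormal(np.log(35.0), 0.4))
                rate_sens = float(rng.lognormal(np.log(300.0), 0.5))
                pot_slope = float(rng.uniform(0.0, 0.6))
                basal_factor = float(rng.lognormal(0.0, 0.2))
                decline = _DECLINE_PER_YEAR[stratum] * float(rng.lognormal(0.0, 0.15))
                hba1c0 = float(rng.normal(58.0, 6.0))

                participants.append(
                    dict(id=pid, trial=trial.name, arm=arm, age_years=round(age, 2),
                         sex=sex, bmi=round(bmi, 2), bsa=round(bsa, 3))
                )

                months = np.asarray(config.visit_months, dtype=float).copy()
                if config.visit_jitter_months > 0 and months.size > 1:
                    jit = rng.uniform(
                        -config.visit_jitter_months, config.visit_jitter_months,
                        months.size - 1,
                    )
                    months[1:] = np.maximum.accumulate(np.maximum(months[1:] + jit, 0.5))
                months = np.round(months, 3)  # tables carry 3-decimal months
                if config.dropout_rate > 0 and rng.random() < config.dropout_rate:
                    cut = rng.uniform(months[0], months[-1])
                    months = months[months <= max(cut, months[0])]

                nb = true_nbgs(
                    months, decline, effect,
                    trial.effect_onset_months, trial.effect_offset_months,
                )
                for m, n in zip(months, nb):
                    beta = beta0 * n
                    if m == 0.0:
                        hba1c = hba1c0
                    else:
                        hba1c = _hba1c_mean(beta) + rng.normal(0.0, 3.0)
                    hba1c = float(np.clip(hba1c, 25.0, 130.0))
                    dose = float(
                        np.clip(_insulin_dose_mean(beta) + rng.normal(0.0, 0.05), 0.05, 2.5)
                    )
                    visits.append(
                        dict(id=pid, month=round(float(m), 3),
                             hba1c_mmol_mol=round(hba1c, 2),
                             insulin_dose_u_kg_day=round(dose, 4))
                    )
                    basal = beta * (_fasting_glucose(beta) - GLUCOSE_THRESHOLD)
                    vt = VisitTruth(
                        beta_gs=beta, rate_sensitivity=rate_sens,
                        potentiation_slope=pot_slope,
                        basal_isr=basal_factor * basal, bsa_m2=bsa,
                        glucose_peak_min=float(rng.uniform(60.0, 90.0)),
                    )
                    rec = forward_mmtt(vt, config, rng)
                    rec.insert(0, "month", round(float(m), 3))
                    rec.insert(0, "id", pid)
                    mmtt.append(rec)
                    truth.append(
                        dict(id=pid, month=round(float(m), 3), stratum=stratum,
                             beta_gs=beta, nbgs=float(n),
                             rate_sensitivity=rate_sens,
                             potentiation_ratio=vt.potentiation_ratio,
                             basal_isr=vt.basal_isr,
                             decline_rate_per_year=decline,
                             treatment_effect=effect)
                    )

    participants = pd.DataFrame(participants)
    visits = pd.DataFrame(visits)
    mmtt = pd.concat(mmtt, ignore_index=True)
    truth = pd.DataFrame(truth)

    corrupt_seed = int(rng.integers(0, 2**31 - 1))
    mmtt, labels = inject_discordant(mmtt, config.discordant_rate, corrupt_seed)
    return SimulatedCohort(participants, visits, mmtt, truth, labels, config)


def inject_discordant(
    mmtt: pd.DataFrame, rate: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Corrupt a random fraction of tests to mimic measurement errors.

    Two corruption modes, chosen at random per selected test: inverting the
    C-peptide excursion relative to glucose (rank correlation flips sign)
    or replacing one mid-test sample with a gross outlier.  Returns the
    corrupted table and a per-test label frame for QC sensitivity analysis.
    """
    if not 0.0 <= rate <= 0.2:
        raise ValueError("discordant rate must be in [0, 0.2]")
    out = mmtt.copy()
    rng = np.random.default_rng(seed)
    labels = []
    for (pid, month), idx in out.groupby(["id", "month"], sort=True).groups.items():
        corrupted = bool(rate > 0 and rng.random() < rate)
        mode = ""
        if corrupted:
            cp = out.loc[idx, "cpeptide_nmol_l"].to_numpy()
            if rng.random() < 0.5:
                mode = "inverted_excursion"
                base = max(cp[0], 1e-3)
                out.loc[idx, "cpeptide_nmol_l"] = base**2 / np.maximum(cp, 1e-3)
            else:
                mode = "outlier_sample"
                j = int(rng.integers(1, cp.size - 1))
                cp = cp.copy()
                cp[j] = cp[j] * 8.0 + 2.0
                out.loc[idx, "cpeptide_nmol_l"] = cp
        labels.append(dict(id=pid, month=month, corrupted=corrupted, mode=mode))
    return out, pd.DataFrame(labels)


def null_config(config: SimConfig) -> SimConfig:
    """The same design with every treatment effect set to 1 (no-effect null)."""
    trials = tuple(replace(t, treatment_effect=1.0) for t in config.trials)
    return replace(config, trials=trials)
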