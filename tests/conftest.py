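from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from betasens import (
    CPeptideKinetics,
    FitOptions,
    SimConfig,
    TrialSpec,
    VisitTruth,
    fit_beta_cell_model,
    fit_cohort,
    forward_mmtt,
    simulate_cohort,
)

settings.register_profile(
    "suite", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


def make_truth(rng: np.random.Generator, **overrides) -> VisitTruth:
    """A physiologically plausible random ground-truth beta cell state."""
    params = dict(
        beta_gs=float(rng.lognormal(np.log(30.0), 0.5)),
        rate_sensitivity=float(rng.lognormal(np.log(300.0), 0.5)),
        potentiation_slope=float(rng.uniform(0.0, 0.6)),
        basal_isr=float(rng.lognormal(np.log(40.0), 0.4)),
        bsa_m2=1.8,
        glucose_peak_min=float(rng.uniform(60.0, 90.0)),
    )
    params.update(overrides)
    return VisitTruth(**params)


@pytest.fixture(scope="session")
def reference_kinetics() -> CPeptideKinetics:
    return CPeptideKinetics.population(age_years=20.0, bsa_m2=1.8)


@pytest.fixture(scope="session")
def small_cohort():
    """A two-trial cohort (one effective drug, one null) used across tests."""
    cfg = SimConfig(
        n_per_arm=12,
        trials=(TrialSpec("drugA", 0.5, 0.0, 12.0), TrialSpec("drugB", 1.0)),
        visit_months=(0.0, 3.0, 6.0, 12.0, 24.0),
        seed=123,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_fits(small_cohort):
    return fit_cohort(small_cohort.mmtt, small_cohort.participants)


@pytest.fixture(scope="session")
def roundtrip_fits(reference_kinetics):
    """Noise-free forward-simulated MMTTs with their model fits and truths."""
    rng = np.random.default_rng(2024)
    cfg = SimConfig(cpeptide_cv=0.0, glucose_cv=0.0)
    out = []
    for _ in range(40):
        truth = make_truth(rng)
        rec = forward_mmtt(truth, cfg)
        fit = fit_beta_cell_model(
            rec["minute"].to_numpy(),
            rec["glucose_mmol_l"].to_numpy(),
            rec["cpeptide_nmol_l"].to_numpy(),
            reference_kinetics,
            FitOptions(bsa_m2=1.8),
        )
        out.append((truth, rec, fit))
    return out
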