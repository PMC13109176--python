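import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from betasens.survival import (
    cox_fit,
    km_estimate,
    logrank,
    ph_check,
    pooled_placebo_frame,
    truncate_at_horizon,
)


# ---------------------------------------------------------------------------
# Kaplan–Meier


def test_km_matches_hand_product_limit():
    """5 subjects, events at 1/2/3, censored at 2.5/4: S = 0.8, 0.6, 0.3."""
    est = km_estimate([1, 2, 2.5, 3, 4], [1, 1, 0, 1, 0])
    surv = dict(zip(est.times, est.survival))
    assert surv[1.0] == pytest.approx(0.8)
    assert surv[2.0] == pytest.approx(0.6)
    assert surv[3.0] == pytest.approx(0.3)
    assert np.all(np.diff(est.survival) <= 1e-12)
    assert est.survival[0] == 1.0
    assert np.all((est.ci_lower - 1e-9 <= est.survival) & (est.survival <= est.ci_upper + 1e-9))


def test_km_all_censored_stays_at_one():
    est = km_estimate([1, 2, 3], [0, 0, 0])
    np.testing.assert_allclose(est.survival, 1.0)


def test_km_all_events_at_one_drops_to_zero():
    est = km_estimate([1, 1, 1], [1, 1, 1])
    assert est.survival[-1] == pytest.approx(0.0)


def test_km_empty_rejected():
    with pytest.raises(ValueError):
        km_estimate([], [])


# ---------------------------------------------------------------------------
# log-rank


def test_logrank_identical_groups_is_null():
    d, e = [1, 2, 3, 4], [1, 1, 0, 1]
    stat, p = logrank(d, e, d, e)
    assert stat == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0)


def _logrank_oracle(da, ea, db, eb):
    """Independent observed-minus-expected computation."""
    da, db = np.asarray(da, float), np.asarray(db, float)
    ea, eb = np.asarray(ea, bool), np.asarray(eb, bool)
    times = np.unique(np.concatenate([da[ea], db[eb]]))
    o_minus_e, var = 0.0, 0.0
    for t in times:
        na = (da >= t).sum()
        nb = (db >= t).sum()
        n = na + nb
        d = ((da == t) & ea).sum() + ((db == t) & eb).sum()
        oa = ((da == t) & ea).sum()
        o_minus_e += oa - d * na / n
        if n > 1:
            var += d * (n - d) / (n - 1) * na * nb / n**2
    stat = o_minus_e**2 / var
    return stat, chi2.sf(stat, 1)


def test_logrank_matches_hand_calculation():
    da, ea = [1, 3, 5], [1, 1, 0]
    db, eb = [2, 4, 6], [1, 0, 1]
    stat, p = logrank(da, ea, db, eb)
    o_stat, o_p = _logrank_oracle(da, ea, db, eb)
    assert stat == pytest.approx(o_stat, rel=1e-9)
    assert p == pytest.approx(o_p, rel=1e-9)
    # frozen from the hand computation: O-E = 0.6, V = 0.74
    assert stat == pytest.approx(0.6**2 / 0.74, rel=1e-9)


def test_logrank_symmetric_in_group_order():
    da, ea = [1, 2, 5, 7], [1, 1, 1, 0]
    db, eb = [3, 4, 6], [1, 0, 1]
    s1, p1 = logrank(da, ea, db, eb)
    s2, p2 = logrank(db, eb, da, ea)
    assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)


def test_logrank_empty_group_rejected():
    with pytest.raises(ValueError):
        logrank([], [], [1], [1])


# ---------------------------------------------------------------------------
# Cox proportional hazards


def _efron_nll_factory(dur, ev, x):
    dur, x = np.asarray(dur, float), np.asarray(x, float)
    ev = np.asarray(ev, bool)

    def nll(beta):
        ll = 0.0
        for t in np.unique(dur[ev]):
            at_event = (dur == t) & ev
            at_risk = dur >= t
            d = at_event.sum()
            theta_r = np.exp(beta * x[at_risk]).sum()
            theta_d = np.exp(beta * x[at_event]).sum()
            ll += beta * x[at_event].sum()
            for ell in range(d):
                ll -= np.log(theta_r - ell / d * theta_d)
        return -ll

    return nll


def test_cox_matches_efron_partial_likelihood_oracle():
    """10-subject tied fixture: coefficient equals an independent
    maximization of the Efron partial likelihood to 1e-3."""
    dur = [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]
    ev = [1, 0, 1, 1, 0, 1, 1, 0, 1, 0]
    x = [1, 1, 1, 0, 0, 1, 0, 0, 1, 0]
    res = minimize_scalar(
        _efron_nll_factory(dur, ev, x), bounds=(-5, 5), method="bounded",
        options={"xatol": 1e-10},
    )
    frame = pd.DataFrame(dict(time_months=dur, event=ev, treated=x))
    fit = cox_fit(frame, covariates=("treated",))
    assert fit.coefficients["treated"] == pytest.approx(res.x, abs=1e-3)
    assert fit.ci_lower["treated"] < fit.hazard_ratios["treated"] < fit.ci_upper["treated"]


def _simulated_frame(rng, n=60, hr=1.0):
    treated = np.repeat([1, 0], n // 2)
    lam = 0.1 * hr**treated
    t = rng.exponential(1 / lam)
    cens = 15.0
    return pd.DataFrame(
        dict(
            time_months=np.minimum(t, cens), event=t <= cens, treated=treated,
            sex=rng.choice(["M", "F"], n), age_years=rng.uniform(5, 45, n),
            bmi=rng.normal(22, 4, n),
        )
    )


def test_cox_hr_invariances():
    """Shifting age leaves the treatment HR unchanged; rescaling BMI leaves
    its per-SD HR unchanged."""
    rng = np.random.default_rng(42)
    frame = _simulated_frame(rng, n=120, hr=0.6)
    fit = cox_fit(frame)
    shifted = frame.assign(age_years=frame["age_years"] + 10.0)
    fit_shift = cox_fit(shifted)
    assert fit_shift.hazard_ratios["treated"] == pytest.approx(
        fit.hazard_ratios["treated"], rel=1e-6
    )
    scaled = frame.assign(bmi=frame["bmi"] * 3.0)
    fit_scaled = cox_fit(scaled)
    assert fit_scaled.hazard_ratios["bmi_per_sd"] == pytest.approx(
        fit.hazard_ratios["bmi_per_sd"], rel=1e-6
    )


def test_cox_missing_covariate_rejected():
    frame = pd.DataFrame(
        dict(time_months=[1, 2, 3, 4], event=[1, 1, 0, 1], treated=[1, 0, 1, 0],
             sex=["M", "F", "M", "F"], age_years=[10.0, np.nan, 30.0, 40.0],
             bmi=[20.0, 21.0, 22.0, 23.0])
    )
    with pytest.raises(ValueError, match="missing"):
        cox_fit(frame)


def test_cox_separation_flagged_not_crash():
    """Complete separation (treated all early events) yields a flagged
    result instead of an exception."""
    frame = pd.DataFrame(
        dict(
            time_months=[1, 1, 1, 1, 10, 10, 10, 10],
            event=[1, 1, 1, 1, 0, 0, 0, 0],
            treated=[1, 1, 1, 1, 0, 0, 0, 0],
        )
    )
    fit = cox_fit(frame, covariates=("treated",))
    assert fit.flagged


# ---------------------------------------------------------------------------
# pooled placebo and horizons


def test_pooled_placebo_concatenates_all_trials():
    events = pd.DataFrame(
        dict(id=[f"p{i}" for i in range(6)], endpoint="nbgs_loss", threshold=0.1,
             time_months=[3, 6, 9, 12, 15, 18], event=[True] * 6)
    )
    participants = pd.DataFrame(
        dict(id=[f"p{i}" for i in range(6)],
             trial=["A", "A", "B", "B", "C", "C"],
             arm=["treatment", "placebo", "treatment", "placebo", "treatment", "placebo"],
             age_years=20.0, sex="F", bmi=22.0, bsa=1.7)
    )
    frame = pooled_placebo_frame(events, participants, "A")
    assert (frame.loc[frame["treated"] == 1, "trial"] == "A").all()
    assert set(frame.loc[frame["treated"] == 0, "trial"]) == {"A", "B", "C"}
    with pytest.raises(ValueError):
        pooled_placebo_frame(events, participants, "missing-trial")


def test_horizon_truncation_recodes_late_events():
    events = pd.DataFrame(
        dict(id=["a", "b"], endpoint="nbgs_loss", threshold=0.1,
             time_months=[10.0, 30.0], event=[True, True])
    )
    out = truncate_at_horizon(events, 24.0)
    assert bool(out.loc[out["id"] == "a", "event"].item())
    assert not bool(out.loc[out["id"] == "b", "event"].item())
    assert out.loc[out["id"] == "b", "time_months"].item() == 24.0


# ---------------------------------------------------------------------------
# proportional hazards diagnostic


def test_ph_check_parallel_under_proportional_hazards():
    rng = np.random.default_rng(3)
    n = 2000
    groups = np.repeat(["a", "b"], n)
    lam = np.where(groups == "a", 0.05, 0.10)
    t = rng.exponential(1 / lam)
    res = ph_check(t, np.ones(2 * n, bool), groups)
    assert res["offset_deviation"] < 0.15


def test_ph_check_identical_groups_coincide():
    rng = np.random.default_rng(4)
    t = rng.exponential(10, 500)
    t = np.concatenate([t, t])
    groups = np.repeat(["a", "b"], 500)
    res = ph_check(t, np.ones(1000, bool), groups)
    np.testing.assert_allclose(res["log_cumhaz"]["a"], res["log_cumhaz"]["b"], atol=1e-9)
    assert res["offset_deviation"] == pytest.approx(0.0, abs=1e-9)


def test_ph_check_detects_crossing_hazards():
    rng = np.random.default_rng(5)
    n = 2000
    # group a: all early events; group b: bimodal late -> log cumhaz cross
    ta = rng.uniform(0.5, 2.0, n)
    tb = np.concatenate([rng.uniform(0.1, 0.3, n // 10), rng.uniform(5, 20, n - n // 10)])
    t = np.concatenate([ta, tb])
    groups = np.repeat(["a", "b"], n)
    res = ph_check(t, np.ones(2 * n, bool), groups)
    assert res["offset_deviation"] > 0.5
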