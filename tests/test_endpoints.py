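import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from betasens.endpoints import (
    EndpointSpec,
    build_event_table,
    cluster_intervals,
    normalize_series,
)
from betasens.synthetic import SimConfig, TrialSpec, simulate_cohort
from betasens.pipeline import fit_cohort


def _fits_frame(rows):
    return pd.DataFrame(rows, columns=["id", "month", "beta_gs", "auc_cp", "flagged"])


def _visits_frame(rows):
    return pd.DataFrame(rows, columns=["id", "month", "hba1c_mmol_mol", "insulin_dose_u_kg_day"])


def _series_frame(pid, months, nbgs=None, naucc=None, hba1c=None):
    n = len(months)
    return pd.DataFrame(
        {
            "id": pid,
            "month": months,
            "nbgs": nbgs if nbgs is not None else [np.nan] * n,
            "naucc": naucc if naucc is not None else [np.nan] * n,
            "hba1c_mmol_mol": hba1c if hba1c is not None else [np.nan] * n,
            "insulin_dose_u_kg_day": [0.3] * n,
        }
    )


# ---------------------------------------------------------------------------
# normalization


def test_normalization_is_one_at_baseline():
    fits = _fits_frame([("a", 0.0, 40.0, 90.0, False), ("a", 6.0, 30.0, 70.0, False)])
    visits = _visits_frame([("a", 0.0, 55.0, 0.3), ("a", 6.0, 50.0, 0.3)])
    series, excluded = normalize_series(fits, visits)
    base = series.loc[series["month"] == 0.0].iloc[0]
    assert base["nbgs"] == 1.0 and base["naucc"] == 1.0
    assert excluded.empty
    follow = series.loc[series["month"] == 6.0].iloc[0]
    assert follow["nbgs"] == pytest.approx(0.75)
    assert follow["naucc"] == pytest.approx(70.0 / 90.0)


def test_constant_beta_gs_normalizes_to_one():
    fits = _fits_frame([("a", m, 33.3, 80.0, False) for m in (0.0, 6.0, 12.0)])
    visits = _visits_frame([("a", m, 50.0, 0.3) for m in (0.0, 6.0, 12.0)])
    series, _ = normalize_series(fits, visits)
    np.testing.assert_allclose(series["nbgs"], 1.0)


@pytest.mark.parametrize(
    "fits_rows, reason",
    [
        ([("a", 6.0, 30.0, 70.0, False)], "no_baseline_test"),
        ([("a", 0.0, 30.0, 70.0, True)], "baseline_flagged"),
        ([("a", 0.0, -1.0, 70.0, False)], "nonpositive_baseline"),
        ([("a", 0.0, 30.0, 0.0, False)], "nonpositive_baseline"),
    ],
)
def test_unusable_baseline_excluded_with_reason(fits_rows, reason):
    visits = _visits_frame([("a", 0.0, 55.0, 0.3)])
    series, excluded = normalize_series(_fits_frame(fits_rows), visits)
    assert series.empty
    assert excluded.iloc[0]["reason"] == reason


def test_flagged_followup_tests_dropped_before_normalization():
    fits = _fits_frame(
        [("a", 0.0, 40.0, 90.0, False), ("a", 6.0, 10.0, 20.0, True), ("a", 12.0, 30.0, 70.0, False)]
    )
    visits = _visits_frame([("a", m, 50.0, 0.3) for m in (0.0, 6.0, 12.0)])
    series, _ = normalize_series(fits, visits)
    assert set(series["month"]) == {0.0, 12.0}


def test_normalization_idempotent():
    fits = _fits_frame([("a", 0.0, 40.0, 90.0, False), ("a", 6.0, 30.0, 45.0, False)])
    visits = _visits_frame([("a", 0.0, 55.0, 0.3), ("a", 6.0, 50.0, 0.3)])
    series, _ = normalize_series(fits, visits)
    refits = series.rename(columns={"nbgs": "beta_gs", "naucc": "auc_cp"})[
        ["id", "month", "beta_gs", "auc_cp"]
    ].assign(flagged=False)
    again, _ = normalize_series(refits, visits)
    np.testing.assert_allclose(again["nbgs"], series["nbgs"])
    np.testing.assert_allclose(again["naucc"], series["naucc"])


def test_true_decline_recovered_through_normalization(monkeypatch):
    """A participant with a true 30% βGS loss by 24 months, zero noise,
    shows estimated nβGS(24) within ±0.05 of the true value (median 0.70)."""
    # decline rate chosen so exp(-r*2) = 0.7 in every stratum
    r = -np.log(0.7) / 2.0
    from betasens import synthetic as syn

    monkeypatch.setattr(syn, "_DECLINE_PER_YEAR", {k: r for k in syn._DECLINE_PER_YEAR})
    cfg = SimConfig(
        n_per_arm=6, trials=(TrialSpec("t", 1.0),),
        visit_months=(0.0, 24.0), cpeptide_cv=0.0, glucose_cv=0.0,
        discordant_rate=0.0, visit_jitter_months=0.0, seed=9,
    )
    cohort = simulate_cohort(cfg)
    truth = cohort.truth
    fits = fit_cohort(cohort.mmtt, cohort.participants)
    series, _ = normalize_series(fits, cohort.visits)
    merged = series.loc[series["month"] == 24.0].merge(
        truth.loc[truth["month"] == 24.0, ["id", "nbgs"]], on="id", suffixes=("_est", "_true")
    )
    np.testing.assert_allclose(merged["nbgs_est"], merged["nbgs_true"], atol=0.05)
    assert truth.loc[truth["month"] == 24.0, "nbgs"].median() == pytest.approx(0.70, abs=0.08)


# ---------------------------------------------------------------------------
# event tables


def test_event_censored_when_never_crossing():
    series = _series_frame("a", [0.0, 6.0, 12.0], nbgs=[1.0, 0.95, 0.92])
    events = build_event_table(series, EndpointSpec("nbgs_loss", 0.10))
    row = events.iloc[0]
    assert not row["event"] and row["time_months"] == 12.0


def test_event_at_first_crossing():
    series = _series_frame("a", [0.0, 6.0], nbgs=[1.0, 0.85])
    events = build_event_table(series, EndpointSpec("nbgs_loss", 0.10))
    row = events.iloc[0]
    assert row["event"] and row["time_months"] == 6.0


def test_hba1c_event_at_threshold():
    series = _series_frame("a", [0.0, 6.0, 12.0], hba1c=[50.0, 53.0, 60.0])
    events = build_event_table(series, EndpointSpec("hba1c_threshold", 53.0))
    row = events.iloc[0]
    assert row["event"] and row["time_months"] == 6.0


def test_unknown_endpoint_rejected():
    with pytest.raises(ValueError, match="unknown endpoint"):
        EndpointSpec("bogus", 0.1)


def _brute_force_events(series, column, crosses):
    """Independent exhaustive scan of every participant's series."""
    out = {}
    for pid, grp in series.groupby("id"):
        post = grp.loc[grp["month"] > 0].sort_values("month")
        if post.empty:
            continue
        hit = None
        for _, row in post.iterrows():
            if crosses(row[column]):
                hit = (row["month"], True)
                break
        out[pid] = hit if hit else (post["month"].iloc[-1], False)
    return out


def test_event_counts_match_brute_force_and_are_monotone(small_cohort, small_cohort_fits):
    """Event count at 50% loss <= at 10% loss; both equal an exhaustive scan."""
    series, _ = normalize_series(small_cohort_fits, small_cohort.visits)
    counts = {}
    for thr in (0.10, 0.50):
        events = build_event_table(series, EndpointSpec("nbgs_loss", thr))
        oracle = _brute_force_events(series, "nbgs", lambda v, t=thr: v <= 1 - t)
        assert len(events) == len(oracle)
        for _, row in events.iterrows():
            t, e = oracle[row["id"]]
            assert row["time_months"] == t and row["event"] == e
        counts[thr] = int(events["event"].sum())
    assert counts[0.50] <= counts[0.10]


def test_events_plus_censored_equals_usable_participants(small_cohort, small_cohort_fits):
    series, excluded = normalize_series(small_cohort_fits, small_cohort.visits)
    usable = series.loc[series["month"] > 0, "id"].nunique()
    for kind, thr in (("nbgs_loss", 0.1), ("naucc_loss", 0.1), ("hba1c_threshold", 53.0)):
        events = build_event_table(series, EndpointSpec(kind, thr))
        assert len(events) == usable
        assert int(events["event"].sum()) + int((~events["event"]).sum()) == usable


# ---------------------------------------------------------------------------
# interval clustering


@pytest.mark.parametrize(
    "month, label",
    [
        (6.0, "(0,6]"), (6.01, "(6,12]"), (0.0, "baseline"), (0.1, "(0,6]"),
        (12.0, "(6,12]"), (29.9, "(24,30]"), (30.0, "(24,30]"), (30.01, "(30,end]"),
        (68.0, "(30,end]"),
    ],
)
def test_interval_boundaries(month, label):
    assert cluster_intervals(month) == label


def _interval_oracle(m):
    if m == 0:
        return "baseline"
    if m <= 6:
        return "(0,6]"
    if m <= 12:
        return "(6,12]"
    if m <= 18:
        return "(12,18]"
    if m <= 24:
        return "(18,24]"
    if m <= 30:
        return "(24,30]"
    return "(30,end]"


@given(st.lists(st.floats(0.0, 80.0), min_size=1, max_size=50))
def test_interval_labels_match_comparison_chain(months):
    labels = cluster_intervals(months)
    for m, lab in zip(months, labels):
        assert lab == _interval_oracle(m)


def test_negative_month_rejected():
    with pytest.raises(ValueError):
        cluster_intervals(-1.0)
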