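"""Time-course comparison of drug-treated arms in positive vs negative trials.

Trials are labelled positive or negative by their primary outcome (a
configuration input, not inferred from the data).  Drug-treated
participants from the two groups are compared per follow-up interval on
nβGS, nAUC_Cp, HbA1c and insulin dose with two-sided Mann–Whitney tests,
one value per participant per interval (the earliest visit in the
interval, to avoid pseudo-replication).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .endpoints import cluster_intervals

__all__ = ["pool_by_outcome", "compare_timecourse", "TIMECOURSE_METRICS"]

TIMECOURSE_METRICS = ("nbgs", "hba1c_mmol_mol", "naucc", "insulin_dose_u_kg_day")


def pool_by_outcome(
    participants: pd.DataFrame, trial_labels: dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split drug-treated participants into positive-trial and
    negative-trial groups.

    ``trial_labels`` maps every trial name to ``"positive"`` or
    ``"negative"``.  Placebo arms are excluded.  Raises when a trial is
    unlabelled, a label is invalid, or either group ends up empty.
    """
    trials = set(participants["trial"].unique())
    missing = trials - set(trial_labels)
    if missing:
        raise ValueError(f"unlabelled trials: {sorted(missing)}")
    bad = {v for v in trial_labels.values()} - {"positive", "negative"}
    if bad:
        raise ValueError(f"invalid trial labels: {sorted(bad)}; use positive|negative")
    treated = participants.loc[participants["arm"] == "treatment"]
    pos = treated.loc[treated["trial"].map(trial_labels) == "positive"]
    neg = treated.loc[treated["trial"].map(trial_labels) == "negative"]
    if pos.empty or neg.empty:
        raise ValueError("both positive and negative groups must be non-empty")
    return pos.copy(), neg.copy()


def compare_timecourse(
    series: pd.DataFrame,
    group_pos: pd.DataFrame,
    group_neg: pd.DataFrame,
    metrics: tuple[str, ...] = TIMECOURSE_METRICS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-interval medians, IQRs and Mann–Whitney comparisons.

    ``series`` is the normalized per-visit table (id, month, metric
    columns).  For every interval and metric the earliest in-interval value
    per participant enters the test.  Intervals where either group is empty
    are reported with NaN statistics rather than raised.
    """
    df = series.loc[series["month"] > 0.0].copy()
    df["interval"] = cluster_intervals(df["month"].to_numpy()).to_numpy()
    membership = {
        **{pid: "positive" for pid in group_pos["id"]},
        **{pid: "negative" for pid in group_neg["id"]},
    }
    df["group"] = df["id"].map(membership)
    df = df.loc[df["group"].notna()]

    interval_order = [lab for lab in df["interval"].unique()]
    interval_order.sort(key=lambda s: float(s.split(",")[0].lstrip("(")))

    rows = []
    for interval in interval_order:
        sub = df.loc[df["interval"] == interval]
        # earliest visit in the interval per participant
        sub = sub.sort_values("month").groupby("id", sort=True).first().reset_index()
        for metric in metrics:
            a = sub.loc[sub["group"] == "positive", metric].dropna().to_numpy()
            b = sub.loc[sub["group"] == "negative", metric].dropna().to_numpy()
            row = dict(interval=interval, metric=metric, n_positive=a.size, n_negative=b.size)
            if a.size == 0 or b.size == 0:
                row.update(
                    median_positive=np.nan, iqr_lo_positive=np.nan, iqr_hi_positive=np.nan,
                    median_negative=np.nan, iqr_lo_negative=np.nan, iqr_hi_negative=np.nan,
                    p_value=np.nan, significant=False,
                )
            else:
                p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
                row.update(
                    median_positive=float(np.median(a)),
                    iqr_lo_positive=float(np.quantile(a, 0.25)),
                    iqr_hi_positive=float(np.quantile(a, 0.75)),
                    median_negative=float(np.median(b)),
                    iqr_lo_negative=float(np.quantile(b, 0.25)),
                    iqr_hi_negative=float(np.quantile(b, 0.75)),
                    p_value=p, significant=bool(p <= alpha),
                )
            rows.append(row)
    return pd.DataFrame(rows)
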