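"""Normalized trajectories and time-to-event responder endpoints.

A participant's follow-up is summarized relative to their own baseline:
nβGS(t) = βGS(t)/βGS(0) and nAUC_Cp(t) = AUC_Cp(t)/AUC_Cp(0).  Three
responder definitions convert trajectories into time-to-event records:

* ``nbgs_loss`` — loss of βGS reaching the threshold fraction of baseline
  (default 10%), i.e. an event at the first visit with nβGS <= 1 - threshold;
* ``naucc_loss`` — the analogous loss of normalized C-peptide AUC;
* ``hba1c_threshold`` — HbA1c at or above 53 mmol/mol (7.0%) after baseline.

Participants who never cross are censored at their last visit.  Flagged
(QC-discordant) tests are dropped before normalization; a participant whose
baseline test is flagged is excluded entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EndpointSpec",
    "HBA1C_THRESHOLD_MMOL_MOL",
    "normalize_series",
    "build_event_table",
    "cluster_intervals",
    "INTERVAL_EDGES",
]

HBA1C_THRESHOLD_MMOL_MOL = 53.0

INTERVAL_EDGES = (0.0, 6.0, 12.0, 18.0, 24.0, 30.0, np.inf)
_INTERVAL_LABELS = ("(0,6]", "(6,12]", "(12,18]", "(18,24]", "(24,30]", "(30,end]")

_ENDPOINT_KINDS = ("nbgs_loss", "hba1c_threshold", "naucc_loss")


@dataclass(frozen=True)
class EndpointSpec:
    kind: str  # nbgs_loss | hba1c_threshold | naucc_loss
    threshold: float = 0.10  # loss fraction, or mmol/mol for hba1c_threshold

    def __post_init__(self) -> None:
        if self.kind not in _ENDPOINT_KINDS:
            raise ValueError(f"unknown endpoint kind {self.kind!r}; one of {_ENDPOINT_KINDS}")
        if self.kind in ("nbgs_loss", "naucc_loss") and not 0.0 < self.threshold < 1.0:
            raise ValueError("loss threshold must be a fraction in (0, 1)")


def normalize_series(fits: pd.DataFrame, visits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant series of nβGS, nAUC_Cp, HbA1c and insulin dose.

    ``fits`` needs columns id, month, beta_gs, auc_cp, flagged; ``visits``
    needs id, month, hba1c_mmol_mol, insulin_dose_u_kg_day.  Flagged fits
    are dropped first.  Participants without a usable baseline (month 0,
    unflagged, βGS > 0 and AUC_Cp > 0) are excluded; the second returned
    frame logs each exclusion with its reason.
    """
    fits = fits.copy()
    fits["flagged"] = fits["flagged"].astype(bool)
    usable = fits.loc[~fits["flagged"]]

    rows, excluded = [], []
    for pid, grp in fits.groupby("id", sort=True):
        base_all = grp.loc[grp["month"] == 0.0]
        if base_all.empty:
            excluded.append(dict(id=pid, reason="no_baseline_test"))
            continue
        base = base_all.loc[~base_all["flagged"]]
        if base.empty:
            excluded.append(dict(id=pid, reason="baseline_flagged"))
            continue
        b = base.iloc[0]
        if not (b["beta_gs"] > 0 and b["auc_cp"] > 0):
            excluded.append(dict(id=pid, reason="nonpositive_baseline"))
            continue
        g = usable.loc[usable["id"] == pid].sort_values("month")
        out = pd.DataFrame(
            {
                "id": pid,
                "month": g["month"].to_numpy(),
                "nbgs": g["beta_gs"].to_numpy() / b["beta_gs"],
                "naucc": g["auc_cp"].to_numpy() / b["auc_cp"],
            }
        )
        rows.append(out)
    series = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["id", "month", "nbgs", "naucc"])
    )
    series = series.merge(
        visits[["id", "month", "hba1c_mmol_mol", "insulin_dose_u_kg_day"]],
        on=["id", "month"],
        how="left",
    )
    return series, pd.DataFrame(excluded, columns=["id", "reason"])


def build_event_table(series: pd.DataFrame, spec: EndpointSpec) -> pd.DataFrame:
    """Time-to-event records: first post-baseline visit crossing the
    endpoint, otherwise censoring at the last visit.

    Participants with no post-baseline visit are dropped (they contribute
    no follow-up time).  Returns columns id, endpoint, threshold,
    time_months, event.
    """
    records = []
    for pid, grp in series.groupby("id", sort=True):
        post = grp.loc[grp["month"] > 0.0].sort_values("month")
        if post.empty:
            continue
        if spec.kind == "nbgs_loss":
            crossed = post["nbgs"] <= 1.0 - spec.threshold
        elif spec.kind == "naucc_loss":
            crossed = post["naucc"] <= 1.0 - spec.threshold
        else:
            crossed = post["hba1c_mmol_mol"] >= spec.threshold
        crossed = crossed.fillna(False).to_numpy()
        if crossed.any():
            t = float(post["month"].to_numpy()[crossed.argmax()])
            event = True
        else:
            t = float(post["month"].iloc[-1])
            event = False
        records.append(
            dict(id=pid, endpoint=spec.kind, threshold=spec.threshold, time_months=t, event=event)
        )
    return pd.DataFrame(
        records, columns=["id", "endpoint", "threshold", "time_months", "event"]
    )


def cluster_intervals(months) -> pd.Series | str:
    """Bin follow-up months into the defined intervals (up to 6, 12, 18, 24,
    30 months and study end), closed on the right; month 0 is ``baseline``.

    Accepts a scalar or a sequence; negative months are invalid.
    """
    scalar = np.isscalar(months)
    m = np.atleast_1d(np.asarray(months, dtype=float))
    if np.any(m < 0):
        raise ValueError("months must be >= 0")
    idx = np.searchsorted(np.asarray(INTERVAL_EDGES[1:-1]), m, side="left")
    labels = np.where(m == 0.0, "baseline", np.asarray(_INTERVAL_LABELS)[idx])
    if scalar:
        return str(labels[0])
    return pd.Series(labels, name="interval")
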