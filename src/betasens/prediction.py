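"""Baseline prediction of clinically significant HbA1c response at 1 year.

A participant responds when HbA1c falls by at least 5.5 mmol/mol (0.5%)
from baseline to the visit nearest 12 months.  The response is modelled by
multivariate logistic regression on four baseline (pre-randomization)
parameters — age, insulin dose, HbA1c and log-transformed βGS — each
standardized to unit SD on the analysis sample so odds ratios correspond to
one-SD increments.  Discrimination is the in-sample ROC AUC with no
optimism correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "LogisticResult",
    "HBA1C_RESPONSE_DELTA_MMOL_MOL",
    "build_outcome",
    "fit_response_model",
    "roc_curve",
    "PREDICTORS",
]

HBA1C_RESPONSE_DELTA_MMOL_MOL = 5.5
PREDICTORS = ("age_years", "insulin_dose_u_kg_day", "hba1c_mmol_mol", "log_beta_gs")


@dataclass
class LogisticResult:
    odds_ratios: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    univariate_odds_ratios: dict[str, float]
    univariate_ci: dict[str, tuple[float, float]]
    roc_auc: float
    n: int
    prevalence: float
    flagged: bool = False
    flag_reason: str = ""
    roc_points: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)
    scores: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)


def build_outcome(
    visits: pd.DataFrame,
    delta_mmol_mol: float = HBA1C_RESPONSE_DELTA_MMOL_MOL,
    window: tuple[float, float] = (6.0, 18.0),
) -> pd.DataFrame:
    """Binary 1-year HbA1c response per participant.

    The 1-year value is the visit nearest month 12 within ``window``
    (half-open on the left, closed on the right).  Outcome is 1 when
    HbA1c(12 m) <= HbA1c(0) - delta (boundary inclusive).  Participants
    lacking a baseline or an in-window visit are omitted.
    """
    lo, hi = window
    rows = []
    for pid, grp in visits.groupby("id", sort=True):
        base = grp.loc[grp["month"] == 0.0, "hba1c_mmol_mol"]
        inwin = grp.loc[(grp["month"] > lo) & (grp["month"] <= hi)]
        if base.empty or inwin.empty:
            continue
        nearest = inwin.iloc[(inwin["month"] - 12.0).abs().argsort().iloc[0]]
        h0 = float(base.iloc[0])
        h12 = float(nearest["hba1c_mmol_mol"])
        rows.append(
            dict(id=pid, hba1c_baseline=h0, hba1c_12m=h12,
                 month_12m=float(nearest["month"]),
                 outcome=int(h12 <= h0 - delta_mmol_mol))
        )
    return pd.DataFrame(
        rows, columns=["id", "hba1c_baseline", "hba1c_12m", "month_12m", "outcome"]
    )


def _fit_logit(x: np.ndarray, y: np.ndarray):
    """MLE logit fit; returns None on separation / singular information."""
    model = sm.Logit(y, sm.add_constant(x, has_constant="add"))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(disp=0, maxiter=200)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        return None


def fit_response_model(features: pd.DataFrame, outcome: pd.Series) -> LogisticResult:
    """Maximum-likelihood logistic fit on per-SD standardized predictors.

    ``features`` columns are used as given except that odds ratios are per
    one SD of each column (SDs computed on the complete-case analysis
    sample).  Returns multivariate and univariate ORs with Wald 95% CIs and
    the in-sample ROC AUC.
    """
    x = features.astype(float).copy()
    y = np.asarray(outcome, dtype=float)
    mask = ~(x.isna().any(axis=1) | np.isnan(y))
    x, y = x.loc[mask], y[mask.to_numpy()]
    if len(x) < 10:
        raise ValueError("too few complete cases for a logistic fit")
    sds = x.std(ddof=1)
    zero_var = sds.index[sds == 0].tolist()
    if zero_var:
        raise ValueError(f"zero-variance predictor(s): {zero_var}")
    z = (x - x.mean()) / sds

    names = list(z.columns)
    res = _fit_logit(z.to_numpy(), y)
    if res is None:
        nan = {n: np.nan for n in names}
        return LogisticResult(
            odds_ratios=nan, ci_lower=dict(nan), ci_upper=dict(nan),
            univariate_odds_ratios=dict(nan),
            univariate_ci={n: (np.nan, np.nan) for n in names},
            roc_auc=np.nan, n=len(z), prevalence=float(y.mean()),
            flagged=True, flag_reason="separation_or_singular_information",
        )
    flagged, reason = False, ""
    if not res.mle_retvals.get("converged", True) or np.any(np.abs(res.params[1:]) > 15):
        flagged, reason = True, "possible_separation_or_nonconvergence"

    params = res.params[1:]
    ci = res.conf_int()[1:]
    with np.errstate(over="ignore"):
        ors = {n: float(np.exp(b)) for n, b in zip(names, params)}
        lo = {n: float(np.exp(c[0])) for n, c in zip(names, ci)}
        hi = {n: float(np.exp(c[1])) for n, c in zip(names, ci)}

    uni_or, uni_ci = {}, {}
    for j, n in enumerate(names):
        r = _fit_logit(z.to_numpy()[:, [j]], y)
        if r is None:
            uni_or[n], uni_ci[n] = np.nan, (np.nan, np.nan)
            continue
        c = r.conf_int()[1]
        with np.errstate(over="ignore"):
            uni_or[n] = float(np.exp(r.params[1]))
            uni_ci[n] = (float(np.exp(c[0])), float(np.exp(c[1])))

    scores = res.predict(sm.add_constant(z.to_numpy(), has_constant="add"))
    points, auc = roc_curve(scores, y.astype(int))
    return LogisticResult(
        odds_ratios=ors, ci_lower=lo, ci_upper=hi,
        univariate_odds_ratios=uni_or, univariate_ci=uni_ci,
        roc_auc=auc, n=len(z), prevalence=float(y.mean()),
        flagged=flagged, flag_reason=reason, roc_points=points, scores=np.asarray(scores),
    )


def roc_curve(scores, labels) -> tuple[pd.DataFrame, float]:
    """Empirical ROC curve and trapezoid AUC.

    Tied scores are grouped into single operating points, which makes the
    trapezoid AUC equal to the midrank Mann–Whitney concordance
    U/(n1*n2).  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("roc_curve requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}), auc
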