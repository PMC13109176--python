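"""Figures: Kaplan–Meier curves with shaded CIs and the four-panel
positive-vs-negative time-course layout."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_km", "plot_timecourse"]

_METRIC_TITLES = {
    "nbgs": "normalized βGS",
    "hba1c_mmol_mol": "HbA1c (mmol/mol)",
    "naucc": "normalized AUC C-peptide",
    "insulin_dose_u_kg_day": "insulin dose (U/kg/day)",
}


def plot_km(km: pd.DataFrame, endpoint: str, out_path: str | Path) -> Path:
    """One panel per trial: treatment vs pooled placebo survival with CIs."""
    sub = km.loc[km["endpoint"] == endpoint]
    trials = sorted(sub["trial"].unique())
    ncol = min(3, max(1, len(trials)))
    nrow = (len(trials) + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    for ax, trial in zip(axes.flat, trials):
        for group, color in (("treatment", "C0"), ("pooled_placebo", "C1")):
            g = sub.loc[(sub["trial"] == trial) & (sub["group"] == group)]
            ax.step(g["time_months"], g["survival"], where="post", color=color, label=group)
            ax.fill_between(
                g["time_months"], g["ci_lower"], g["ci_upper"],
                step="post", alpha=0.2, color=color,
            )
        p = sub.loc[sub["trial"] == trial, "logrank_p"].iloc[0]
        ax.set_title(f"{trial} (log-rank p={p:.2g})")
        ax.set_xlabel("months")
        ax.set_ylabel("event-free fraction")
        ax.set_ylim(0, 1.02)
        ax.legend(fontsize=7)
    for ax in axes.flat[len(trials):]:
        ax.axis("off")
    fig.suptitle(endpoint)
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def plot_timecourse(tc: pd.DataFrame, out_path: str | Path) -> Path:
    """Four panels (nβGS, HbA1c, nAUC_Cp, insulin dose) of group medians
    with IQR bars; asterisks mark intervals with p <= 0.05."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for ax, metric in zip(axes.flat, _METRIC_TITLES):
        g = tc.loc[tc["metric"] == metric]
        x = range(len(g))
        for side, color in (("positive", "C0"), ("negative", "C1")):
            med = g[f"median_{side}"]
            ax.errorbar(
                x, med,
                yerr=[med - g[f"iqr_lo_{side}"], g[f"iqr_hi_{side}"] - med],
                marker="o", capsize=3, label=side, color=color,
            )
        for i, (_, row) in enumerate(g.iterrows()):
            if row["significant"]:
                ax.annotate("*", (i, max(row["iqr_hi_positive"], row["iqr_hi_negative"])),
                            ha="center", fontsize=14)
        ax.set_xticks(list(x), g["interval"], rotation=30, fontsize=8)
        ax.set_title(_METRIC_TITLES[metric])
        ax.legend(fontsize=8)
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
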