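"""Time course of nβGS, HbA1c, nAUC_Cp and insulin dose: positive vs
negative trials (drug-treated arms only), per follow-up interval, with
Mann-Whitney comparisons.  Writes results/timecourse.csv and the
four-panel figure.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import FIGURES, RESULTS, SCRATCH, SEED, TRIAL_LABELS

from betasens import io as bio
from betasens.plots import plot_timecourse
from betasens.timecourse import compare_timecourse, pool_by_outcome

import pandas as pd


def main() -> None:
    participants = bio.read_table(SCRATCH / "participants.csv", "participants")
    series = pd.read_csv(SCRATCH / "normalized_series.csv", comment="#")
    pos, neg = pool_by_outcome(participants, TRIAL_LABELS)
    tc = compare_timecourse(series, pos, neg)
    bio.write_table(tc.round(4), RESULTS / "timecourse.csv", SEED)
    plot_timecourse(tc, FIGURES / "timecourse.png")

    nbgs = tc.loc[tc["metric"] == "nbgs"]
    print(f"positive-trial treated n={len(pos)}, negative-trial treated n={len(neg)}")
    print("nβGS medians (positive vs negative) by interval:")
    for _, row in nbgs.iterrows():
        star = "*" if row["significant"] else " "
        print(f"  {row['interval']}: {row['median_positive']:.2f} vs "
              f"{row['median_negative']:.2f} (p={row['p_value']:.3g}){star}")
    first_sig = {m: None for m in tc["metric"].unique()}
    for m in first_sig:
        sig = tc.loc[(tc["metric"] == m) & tc["significant"], "interval"]
        first_sig[m] = sig.iloc[0] if not sig.empty else "never"
    print("earliest interval with a significant group difference:", first_sig)


if __name__ == "__main__":
    main()
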