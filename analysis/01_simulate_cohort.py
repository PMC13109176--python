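"""Simulate the nine-trial cohort with known ground truth.

Writes the raw trial tables (participants, visits, MMTT samples, ground
truth, corruption labels) under scratch/cohort/ and prints cohort
bookkeeping.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import SCRATCH, SIM

from betasens import io as bio
from betasens.synthetic import simulate_cohort


def main() -> None:
    cohort = simulate_cohort(SIM)
    h = bio.config_hash(str(SIM))
    for name, df in (
        ("participants", cohort.participants), ("visits", cohort.visits),
        ("mmtt", cohort.mmtt), ("ground_truth", cohort.truth),
        ("discordant_labels", cohort.discordant_labels),
    ):
        bio.write_table(df, SCRATCH / f"{name}.csv", SIM.seed, h)
    n_tests = cohort.mmtt.groupby(["id", "month"]).ngroups
    print(f"simulated {len(cohort.participants)} participants in {len(SIM.trials)} trials")
    print(f"{n_tests} MMTTs ({n_tests / len(cohort.participants):.1f} per participant), "
          f"{int(cohort.discordant_labels['corrupted'].sum())} deliberately discordant "
          f"({100 * cohort.discordant_labels['corrupted'].mean():.1f}%)")
    strata = cohort.truth.drop_duplicates("id")["stratum"].value_counts()
    print("age strata:", dict(strata))


if __name__ == "__main__":
    main()
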