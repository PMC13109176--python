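"""Shared configuration of the analysis scripts.

A nine-trial synthetic cohort emulating a mixed portfolio of stage 3
type 1 diabetes immunotherapy studies: five drugs slow (or halt) the
beta cell decline with different effect windows, four are null.  Raw
simulated tables live under scratch/ (regenerated on demand); derived
results go to results/.
"""

from pathlib import Path

from betasens.synthetic import SimConfig, TrialSpec

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"
FIGURES = RESULTS / "figures"

SEED = 7

TRIALS = (
    TrialSpec("drugA", 0.3, 0.0, 24.0),
    TrialSpec("drugB", 0.4, 0.0, 24.0),
    TrialSpec("drugC", 0.5, 0.0, 12.0),
    TrialSpec("drugD", 0.5, 3.0, 24.0),
    TrialSpec("drugE", 0.6, 0.0, 24.0),
    TrialSpec("drugF", 1.0),
    TrialSpec("drugG", 1.0),
    TrialSpec("drugH", 1.0),
    TrialSpec("drugI", 1.0),
)

#: primary-outcome labels used by the positive-vs-negative comparison
TRIAL_LABELS = {
    "drugA": "positive", "drugB": "positive", "drugC": "positive",
    "drugD": "positive", "drugE": "positive",
    "drugF": "negative", "drugG": "negative", "drugH": "negative",
    "drugI": "negative",
}

SIM = SimConfig(n_per_arm=20, trials=TRIALS, seed=SEED)
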