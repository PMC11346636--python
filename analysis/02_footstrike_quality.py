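"""Score foot-strike detection + cleanup against generator ground truth.

Reads the separated cohort written by 01_simulate_cohorts.py, runs signal
conditioning and the full foot-strike stage (AP-peak candidate detection,
extra-prediction removal, missed-step insertion), and scores the cleaned
strikes against the known strike times at a 100 ms tolerance.  Writes
per-trial precision/recall/F1 and cleanup counts to
results/footstrike_quality.csv.
"""

import os
import numpy as np
import pandas as pd

from gaitconf.footstrike import clean_footstrikes, detect_candidates, match_strikes
from gaitconf.preprocess import load_trial, preprocess_trial

SCRATCH = os.path.join(os.path.dirname(__file__), "..", "scratch", "analysis")
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    indir = os.path.join(SCRATCH, "separated")
    manifest = pd.read_csv(os.path.join(indir, "cohort.csv"))
    rows = []
    for pid in manifest["participant_id"]:
        trial = preprocess_trial(load_trial(os.path.join(indir, f"{pid}.csv")))
        truth = pd.read_csv(os.path.join(indir, f"{pid}_truth.csv"))
        cands = detect_candidates(trial)
        cleaned = clean_footstrikes(cands, trial)
        tp, fp, fn = match_strikes(
            cleaned.strikes / trial.rate, truth["strike_time_s"].to_numpy(), 0.1
        )
        rows.append(
            {
                "participant_id": pid,
                "n_true": len(truth),
                "n_candidates": len(cands),
                "n_cleaned": len(cleaned),
                "n_inserted": int(np.sum(cleaned.source == "inserted")),
                "precision": tp / (tp + fp) if tp + fp else np.nan,
                "recall": tp / (tp + fn) if tp + fn else np.nan,
                "f1": 2 * tp / (2 * tp + fp + fn) if tp else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(os.path.join(RESULTS, "footstrike_quality.csv"), index=False)
    print(table[["precision", "recall", "f1"]].describe().round(4).to_string())
    print(f"\nmean F1 at 100 ms tolerance: {table['f1'].mean():.4f}")
    print(f"wrote {os.path.join(RESULTS, 'footstrike_quality.csv')}")


if __name__ == "__main__":
    main()
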