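"""Extract the 248-feature trial vectors for both cohorts.

Reads the trial CSVs written by 01_simulate_cohorts.py, runs the full
per-trial pipeline (preprocess, foot-strike cleanup, step segmentation, 62
per-step features, min/max/mean/SD aggregation) and writes one feature
matrix per cohort to scratch/analysis/features_<cohort>.csv.  A small
per-class summary of a few interpretable features goes to
results/feature_summary.csv.
"""

import os

import pandas as pd

from gaitconf.pipeline import RunConfig, process_trial

SCRATCH = os.path.join(os.path.dirname(__file__), "..", "scratch", "analysis")
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")

SHOWCASE = [
    "cadence__mean",
    "step_time_right__sd",
    "symmetry_index__mean",
    "sd_ml__mean",
    "reoh_ap__mean",
]


def main():
    summaries = []
    for name in ("separated", "null"):
        indir = os.path.join(SCRATCH, name)
        manifest = pd.read_csv(os.path.join(indir, "cohort.csv"))
        cfg = RunConfig(input_dir=indir, output_dir=SCRATCH)
        vectors = {}
        for pid in manifest["participant_id"]:
            *_, vector, counts = process_trial(
                os.path.join(indir, f"{pid}.csv"), cfg, participant_id=pid
            )
            vectors[pid] = vector
        features = pd.DataFrame(vectors).T
        features.index.name = "participant_id"
        out = os.path.join(SCRATCH, f"features_{name}.csv")
        features.to_csv(out)
        print(f"{name}: {features.shape[0]} trials x {features.shape[1]} features -> {out}")

        merged = features[SHOWCASE].join(
            manifest.set_index("participant_id")["class"]
        )
        by_class = merged.groupby("class").mean().assign(cohort=name)
        summaries.append(by_class)

    summary = pd.concat(summaries)
    print("\nper-class means of selected features:")
    print(summary.round(4).to_string())
    summary.to_csv(os.path.join(RESULTS, "feature_summary.csv"))
    print(f"\nwrote {os.path.join(RESULTS, 'feature_summary.csv')}")


if __name__ == "__main__":
    main()
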