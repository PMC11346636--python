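"""Recompute classification metrics from the published confusion matrix.

The published study of 58 people with lower limb amputation reports the
balance-confidence confusion matrix (true high predicted high = 12,
high/low = 7, low/high = 4, low/low = 35).  This driver feeds those counts
through the package's metric computation and writes the result to
results/published_metrics.json.
"""

import json
import os

from gaitconf.model import ConfusionMatrix, compute_metrics

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    cm = ConfusionMatrix(tp=12, fn=7, fp=4, tn=35)
    metrics = compute_metrics(cm)
    payload = {
        "confusion": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn},
        "n_participants": cm.total,
        "n_correct": cm.correct,
        "metrics_pct": metrics.as_dict(),
    }
    os.makedirs(RESULTS, exist_ok=True)
    with open(os.path.join(RESULTS, "published_metrics.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    print(json.dumps(payload, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
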