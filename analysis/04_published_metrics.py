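#!/usr/bin/env python
"""Recompute every evaluation metric from the study's printed confusion
matrices.

The original study never deposited its recordings, but its printed 4x4
confusion matrices (EEG, GSR, PPG and the three-modality fusion over 84
sessions) fully determine accuracy, Cohen's kappa and the per-class
rates.  This driver recomputes them from the shipped CSV inputs and
writes results/published_metrics.json.

Note the GSR/PPG/fusion matrices are printed transposed relative to the
EEG one (their column sums, not row sums, match the 9/22/40/13 class
counts); accuracy and kappa are transpose-invariant, so they are
reported for all four, while per-class rates are reported only for the
row-consistent EEG matrix.
"""

import json
from pathlib import Path

from temsense.evaluation import accuracy, cohen_kappa, per_class_rates
from temsense.reference import STUDY_MODALITIES, load_study_confusion

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out: dict = {}
    for modality in STUDY_MODALITIES:
        cm = load_study_confusion(modality)
        out[modality] = {
            "n": cm.n,
            "accuracy_pct": round(accuracy(cm), 2),
            "kappa": round(cohen_kappa(cm), 4),
        }
        print(f"{modality:8s} accuracy {out[modality]['accuracy_pct']:6.2f}%  "
              f"kappa {out[modality]['kappa']:.4f}")

    rates = per_class_rates(load_study_confusion("eeg"))
    out["eeg"]["per_class"] = {
        c: {
            "sensitivity_pct": round(100 * rates.loc[c, "sensitivity"], 1),
            "specificity_pct": round(100 * rates.loc[c, "specificity"], 1),
        }
        for c in rates.index
    }
    print("\nEEG per-class rates:")
    print((100 * rates).round(1).to_string())

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "published_metrics.json").write_text(
        json.dumps(out, indent=2) + "\n"
    )


if __name__ == "__main__":
    main()
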