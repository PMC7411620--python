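#!/usr/bin/env python
"""Generate the default synthetic dataset: 21 participants x 4 clips.

Writes the session waveform CSVs (large) under scratch/synthetic_sessions/
and the reproducibility manifest plus quadrant labels under results/.
The class split is fixed at happy 40, angry 13, sad 22, relaxed 9.
"""

import json
from pathlib import Path

from temsense.io import write_session_csv
from temsense.labeling import label_dataset
from temsense.synthgen import SynthConfig, generate_dataset

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = SynthConfig()
    sessions, truths, manifest = generate_dataset(cfg)

    sess_dir = ROOT / "scratch" / "synthetic_sessions"
    sess_dir.mkdir(parents=True, exist_ok=True)
    for rec in sessions:
        write_session_csv(rec, sess_dir / f"{rec.participant_id}_{rec.clip_id}.csv")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    labels, counts = label_dataset([t.rating for t in truths])
    with open(results / "labels.csv", "w") as fh:
        fh.write("participant_id,clip_id,valence,arousal,label\n")
        for t, lab in zip(truths, labels):
            fh.write(
                f"{t.participant_id},{t.clip_id},{t.rating.valence},"
                f"{t.rating.arousal},{lab}\n"
            )

    print(f"wrote {len(sessions)} sessions to {sess_dir}")
    print(f"class counts (relaxed, sad, happy, angry): {tuple(counts.values())}")
    assert tuple(counts.values()) == (9, 22, 40, 13)


if __name__ == "__main__":
    main()
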