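#!/usr/bin/env python
"""Extract the 84 x 36 feature matrix from the synthetic sessions.

Loads the waveforms written by 01_simulate.py when present (regenerates
them deterministically otherwise), Savitzky-Golay smooths every channel,
and computes the 30 EEG + 4 GSR + 2 PPG features per session.  Writes
results/features.csv with the canonical feature-name header.
"""

from pathlib import Path

from temsense.fusion_classify import build_feature_matrix
from temsense.io import load_sessions_dir
from temsense.synthgen import SynthConfig, generate_dataset

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    sess_dir = ROOT / "scratch" / "synthetic_sessions"
    if sess_dir.is_dir() and any(sess_dir.glob("*.csv")):
        sessions = load_sessions_dir(sess_dir, fs=256.0)
        print(f"loaded {len(sessions)} sessions from {sess_dir}")
    else:
        sessions, _, _ = generate_dataset(SynthConfig())
        print("scratch sessions not found; regenerated from the default seed")

    features = build_feature_matrix(sessions)
    out = ROOT / "results" / "features.csv"
    out.parent.mkdir(exist_ok=True)
    features.to_csv(out, float_format="%.10g")
    print(f"wrote {features.shape[0]} x {features.shape[1]} feature matrix to {out}")
    assert features.shape == (84, 36)


if __name__ == "__main__":
    main()
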