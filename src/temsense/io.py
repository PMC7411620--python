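"""File formats, run configuration and the end-to-end pipeline driver.

Formats:

* session CSV — columns ``t_s, TP9, AF7, AF8, TP10, GSR, PPG``, one row
  per sample at a uniform rate;
* ``manifest.json`` — session table with seeds, ground truth and SAM
  ratings for a generated dataset;
* feature matrix CSV — header = canonical feature names, one row per
  session;
* metrics JSON and confusion CSV per modality mask.

:func:`run_pipeline` ties the stages together: simulate (or load),
extract, label, cross-validate all seven modality masks, evaluate and
write artifacts.  Identical configuration reproduces byte-identical
reports.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import confusion, metric_report
from .fusion_classify import (
    ClassifierConfig,
    build_feature_matrix,
    cross_validate,
    fuse,
)
from .labeling import SAMRating, label_dataset
from .synthgen import EEG_CHANNELS, SessionRecording, SynthConfig, generate_dataset

__all__ = [
    "SESSION_COLUMNS",
    "MODALITY_MASKS",
    "RunConfig",
    "read_session_csv",
    "write_session_csv",
    "run_pipeline",
]

SESSION_COLUMNS: tuple[str, ...] = ("t_s",) + EEG_CHANNELS + ("GSR", "PPG")

#: The seven nonempty modality masks, in reporting order.
MODALITY_MASKS: tuple[tuple[str, ...], ...] = (
    ("eeg",),
    ("gsr",),
    ("ppg",),
    ("eeg", "gsr"),
    ("eeg", "ppg"),
    ("gsr", "ppg"),
    ("eeg", "gsr", "ppg"),
)


def mask_name(mask) -> str:
    return "+".join(mask)


@dataclass
class RunConfig:
    """Everything one reproduction run needs."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    data_dir: str | None = None  # load sessions from CSVs instead of simulating
    smooth: bool = True
    write_sessions: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = SynthConfig(**raw.get("synth", {}))
        classifier = ClassifierConfig(**raw.get("classifier", {}))
        extra = {
            k: raw[k]
            for k in ("data_dir", "smooth", "write_sessions")
            if k in raw
        }
        return cls(synth=synth, classifier=classifier, **extra)


def write_session_csv(recording: SessionRecording, path) -> None:
    """Write one session as a ``t_s, TP9, AF7, AF8, TP10, GSR, PPG`` CSV."""
    t = np.arange(recording.n_samples) / recording.fs
    df = pd.DataFrame({"t_s": t})
    for name in EEG_CHANNELS:
        df[name] = recording.eeg[name]
    df["GSR"] = recording.gsr
    df["PPG"] = recording.ppg
    df.to_csv(path, index=False, float_format="%.10g")


def read_session_csv(
    path, declared_fs: float | None = None
) -> SessionRecording:
    """Load a session CSV, inferring the rate from the median time step.

    The time column must be uniform: every step within 1% of the median,
    and (when ``declared_fs`` is given) the inferred rate within 1% of
    the declared one.  Participant and clip identifiers are taken from
    the file stem ``<participant>_<clip>.csv`` when it matches, else the
    stem itself is used for both.
    """
    df = pd.read_csv(path)
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"session CSV {path} is missing columns: {missing}")
    if len(df) < 2:
        raise ValueError(f"session CSV {path} is empty or single-row")
    dt = np.diff(df["t_s"].to_numpy())
    if np.any(dt <= 0):
        raise ValueError("time column must be strictly increasing")
    med = float(np.median(dt))
    if np.any(np.abs(dt - med) > 0.01 * med):
        raise ValueError("non-uniform sampling beyond 1% tolerance")
    fs = 1.0 / med
    if declared_fs is not None and abs(fs - declared_fs) > 0.01 * declared_fs:
        raise ValueError(f"inferred fs {fs:.3f} Hz != declared {declared_fs} Hz")
    stem = Path(path).stem
    participant, _, clip = stem.partition("_")
    return SessionRecording(
        participant_id=participant or stem,
        clip_id=clip or stem,
        fs=declared_fs if declared_fs is not None else fs,
        eeg={name: df[name].to_numpy(dtype=float) for name in EEG_CHANNELS},
        gsr=df["GSR"].to_numpy(dtype=float),
        ppg=df["PPG"].to_numpy(dtype=float),
    )


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_sessions_dir(data_dir, fs: float | None = None) -> list[SessionRecording]:
    paths = sorted(Path(data_dir).glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no session CSVs under {data_dir}")
    return [read_session_csv(p, declared_fs=fs) for p in paths]


def run_pipeline(config: RunConfig, out_dir) -> dict[str, dict]:
    """Run simulate/load -> extract -> label -> classify -> evaluate.

    Writes under ``out_dir``: ``manifest.json`` (when simulating),
    ``features.csv``, ``labels.csv``, one ``metrics_<mask>.json`` and
    ``confusion_<mask>.csv`` per modality mask, and ``run_log.json``
    echoing all parameters and seeds.  Returns the metric reports keyed
    by mask name.  On failure, partially written artifacts are removed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        if config.data_dir is not None:
            sessions = load_sessions_dir(config.data_dir, fs=config.synth.fs)
            ratings = _read_ratings(
                Path(config.data_dir) / "ratings.csv", sessions
            )
        else:
            sessions, truths, manifest = generate_dataset(config.synth)
            ratings = [t.rating for t in truths]
            p = out / "manifest.json"
            _json_dump(manifest, p)
            written.append(p)
        if config.write_sessions:
            sess_dir = out / "sessions"
            sess_dir.mkdir(exist_ok=True)
            for rec in sessions:
                sp = sess_dir / f"{rec.participant_id}_{rec.clip_id}.csv"
                write_session_csv(rec, sp)
                written.append(sp)

        labels, counts = label_dataset(ratings)
        features = build_feature_matrix(sessions, smooth=config.smooth)
        meta = pd.DataFrame(
            {
                "participant_id": [s.participant_id for s in sessions],
                "clip_id": [s.clip_id for s in sessions],
                "valence": [r.valence for r in ratings],
                "arousal": [r.arousal for r in ratings],
                "label": labels,
            }
        )
        p = out / "features.csv"
        features.to_csv(p, float_format="%.10g")
        written.append(p)
        p = out / "labels.csv"
        meta.to_csv(p, index=False)
        written.append(p)

        reports: dict[str, dict] = {}
        for mask in MODALITY_MASKS:
            name = mask_name(mask)
            X = fuse(features, mask)
            cv = cross_validate(X, np.array(labels), config.classifier)
            reports[name] = metric_report(cv)
            p = out / f"metrics_{name.replace('+', '_')}.json"
            _json_dump(reports[name], p)
            written.append(p)
            p = out / f"confusion_{name.replace('+', '_')}.csv"
            confusion(cv).to_frame().to_csv(p)
            written.append(p)

        log = {
            "synth": _asdict(config.synth),
            "classifier": dataclasses.asdict(config.classifier),
            "smooth": config.smooth,
            "class_counts": counts,
            "masks": [mask_name(m) for m in MODALITY_MASKS],
        }
        p = out / "run_log.json"
        _json_dump(log, p)
        written.append(p)
        return reports
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _read_ratings(path: Path, sessions: list[SessionRecording]) -> list[SAMRating]:
    """Read ``ratings.csv`` (participant_id, clip_id, valence, arousal)
    and align it to the session order."""
    df = pd.read_csv(path).set_index(["participant_id", "clip_id"])
    try:
        return [
            SAMRating(int(df.loc[s.key, "valence"]), int(df.loc[s.key, "arousal"]))
            for s in sessions
        ]
    except KeyError as e:
        raise ValueError(f"ratings.csv is missing a session: {e}") from e


def _asdict(obj) -> dict:
    d = dataclasses.asdict(obj)
    for k, v in list(d.items()):
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
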