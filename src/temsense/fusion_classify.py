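"""Feature fusion and KNN emotion classification under cross-validation.

Each session is described by up to 36 features — 30 EEG asymmetry/
correlation values, 4 GSR statistics and 2 PPG cardiac values — and
modality-level fusion simply concatenates the selected modalities'
columns (in EEG, GSR, PPG order) before a single classifier sees them.
Classification is k-nearest-neighbor with Euclidean distance on
z-scored features: the raw columns mix microvolts squared, unitless
ratios and milliseconds, so unscaled distances would be dominated by
whichever modality happens to have the largest numeric range.

Evaluation uses seeded stratified 10-fold cross-validation.  The
normalization statistics are refit on each training fold only, so no
information from a held-out session ever reaches the model that
predicts it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .features_eeg import EEG_FEATURE_NAMES, extract_eeg_features
from .features_gsr_ppg import (
    GSR_FEATURE_NAMES,
    PPG_FEATURE_NAMES,
    detect_pulse_peaks,
    gsr_features,
    heart_rate,
    hrv,
)
from .labeling import EMOTIONS
from .preprocess import savgol_smooth
from .synthgen import SessionRecording

__all__ = [
    "MODALITY_ORDER",
    "MODALITY_FEATURES",
    "ALL_FEATURE_NAMES",
    "ClassifierConfig",
    "CVResult",
    "extract_session_features",
    "build_feature_matrix",
    "fuse",
    "knn_predict",
    "cross_validate",
]

MODALITY_ORDER: tuple[str, ...] = ("eeg", "gsr", "ppg")
MODALITY_FEATURES: dict[str, tuple[str, ...]] = {
    "eeg": EEG_FEATURE_NAMES,
    "gsr": GSR_FEATURE_NAMES,
    "ppg": PPG_FEATURE_NAMES,
}
#: Canonical 36-column order of the fused feature vector.
ALL_FEATURE_NAMES: tuple[str, ...] = (
    EEG_FEATURE_NAMES + GSR_FEATURE_NAMES + PPG_FEATURE_NAMES
)


@dataclass(frozen=True)
class ClassifierConfig:
    """KNN and cross-validation settings."""

    k: int = 3
    distance: str = "euclidean"
    n_folds: int = 10
    seed: int = 0
    normalize: bool = True
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class CVResult:
    """Per-session cross-validated predictions.

    ``proba`` rows are neighbor-vote fractions in canonical class order
    (:data:`~temsense.labeling.EMOTIONS`); ``priors`` rows are the class
    frequencies of the training fold that produced each prediction
    (needed by the nominal error statistics).
    """

    fold_id: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    proba: np.ndarray
    priors: np.ndarray
    classes: tuple[str, ...] = EMOTIONS
    config: ClassifierConfig = field(default_factory=ClassifierConfig)

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.y_true == self.y_pred))

    def __len__(self) -> int:
        return len(self.y_true)


def extract_session_features(
    recording: SessionRecording, smooth: bool = True
) -> dict[str, float]:
    """All 36 features of one session, keyed by canonical names.

    When ``smooth`` is true (default) every channel is Savitzky-Golay
    filtered before feature extraction, mirroring the pre-processing of
    the acquisition pipeline.
    """
    if smooth:
        recording = SessionRecording(
            participant_id=recording.participant_id,
            clip_id=recording.clip_id,
            fs=recording.fs,
            eeg={k: savgol_smooth(v) for k, v in recording.eeg.items()},
            gsr=savgol_smooth(recording.gsr),
            ppg=savgol_smooth(recording.ppg),
        )
    out = dict(extract_eeg_features(recording))
    out.update(gsr_features(recording.gsr))
    peaks = detect_pulse_peaks(recording.ppg, recording.fs)
    out["ppg_hr"] = heart_rate(peaks)
    out["ppg_hrv"] = hrv(peaks)
    return out


def build_feature_matrix(
    sessions: list[SessionRecording], smooth: bool = True
) -> pd.DataFrame:
    """Stack per-session feature vectors into a sessions x 36 DataFrame.

    The index is (participant_id, clip_id); columns follow
    :data:`ALL_FEATURE_NAMES`.
    """
    rows = {s.key: extract_session_features(s, smooth=smooth) for s in sessions}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["participant_id", "clip_id"])
    return df[list(ALL_FEATURE_NAMES)]


def fuse(feature_matrix: pd.DataFrame, modalities) -> pd.DataFrame:
    """Select the columns of the requested modalities, in canonical order.

    ``modalities`` is any nonempty subset of {"eeg", "gsr", "ppg"}; all
    seven masks are supported.
    """
    modalities = set(modalities)
    unknown = modalities - set(MODALITY_ORDER)
    if unknown or not modalities:
        raise ValueError(f"modalities must be a nonempty subset of {MODALITY_ORDER}")
    cols = [
        name
        for m in MODALITY_ORDER
        if m in modalities
        for name in MODALITY_FEATURES[m]
    ]
    missing = [c for c in cols if c not in feature_matrix.columns]
    if missing:
        raise ValueError(f"feature matrix is missing columns: {missing}")
    if feature_matrix[cols].isna().any().any():
        raise ValueError("feature matrix contains missing values")
    return feature_matrix[cols]


def _zscore_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0  # constant columns contribute no distance either way
    return mu, sd


def _vote(
    neighbor_labels: np.ndarray, classes: tuple[str, ...]
) -> tuple[str, np.ndarray]:
    """Vote fractions over classes; ties go to the nearest neighbor's class
    among the tied classes (neighbor_labels is distance-ordered)."""
    proba = np.array([np.mean(neighbor_labels == c) for c in classes])
    top = proba.max()
    tied = {classes[i] for i in np.flatnonzero(proba == top)}
    if len(tied) == 1:
        return tied.pop(), proba
    for lab in neighbor_labels:
        if lab in tied:
            return str(lab), proba
    raise AssertionError("unreachable: some tied class must appear among neighbors")


def knn_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    query: np.ndarray,
    config: ClassifierConfig = ClassifierConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Classify query rows against a training set by k-nearest-neighbor vote.

    Returns ``(labels, proba)`` with probabilities = vote fractions in
    canonical class order.  Features are z-scored with training-set
    statistics when ``config.normalize`` is set.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y)
    query = np.atleast_2d(np.asarray(query, dtype=float))
    if config.k >= len(train_X) + 1:
        raise ValueError(f"k={config.k} must be smaller than the training size")
    if config.normalize:
        mu, sd = _zscore_params(train_X)
        train_X = (train_X - mu) / sd
        query = (query - mu) / sd
    nn = NearestNeighbors(n_neighbors=config.k, metric=config.distance)
    nn.fit(train_X)
    _, idx = nn.kneighbors(query)
    labels = []
    proba = np.empty((len(query), len(EMOTIONS)))
    for i, neighbor_idx in enumerate(idx):
        lab, p = _vote(train_y[neighbor_idx], EMOTIONS)
        labels.append(lab)
        proba[i] = p
    return np.array(labels), proba


def _stratified_fold_ids(labels: np.ndarray, n_folds: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Seeded stratified assignment by dealing each class round-robin.

    Shuffled members of each class are dealt consecutively across folds,
    carrying the dealing position from class to class, so fold sizes
    differ by at most one and each class is spread maximally evenly.
    Handles classes with fewer members than folds (some test folds then
    simply lack that class).
    """
    fold_id = np.empty(len(labels), dtype=int)
    pos = 0
    for c in EMOTIONS:
        members = np.flatnonzero(labels == c)
        rng.shuffle(members)
        for m in members:
            fold_id[m] = pos % n_folds
            pos += 1
    return fold_id


def cross_validate(
    X, labels, config: ClassifierConfig = ClassifierConfig()
) -> CVResult:
    """Stratified k-fold cross-validated KNN predictions.

    ``X`` may be a DataFrame (rows = sessions) or array.  Fold
    assignment is seeded by ``config.seed``; z-scoring is refit on each
    training fold.  Every session is predicted exactly once by a model
    that never saw it.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    if n < config.n_folds:
        raise ValueError("need at least n_folds sessions")
    rng = np.random.default_rng(config.seed)
    if config.stratified:
        fold_id = _stratified_fold_ids(labels, config.n_folds, rng)
    else:
        fold_id = rng.permutation(n) % config.n_folds

    y_pred = np.empty(n, dtype=object)
    proba = np.empty((n, len(EMOTIONS)))
    priors = np.empty((n, len(EMOTIONS)))
    for f in range(config.n_folds):
        test = fold_id == f
        train = ~test
        if not test.any():
            continue
        train_y = labels[train]
        absent = [c for c in EMOTIONS if c not in train_y]
        if absent:
            warnings.warn(f"fold {f}: classes absent from training fold: {absent}")
        pred, p = knn_predict(X[train], train_y, X[test], config)
        y_pred[test] = pred
        proba[test] = p
        priors[test] = [np.mean(train_y == c) for c in EMOTIONS]
    return CVResult(
        fold_id=fold_id,
        y_true=labels.astype(object),
        y_pred=y_pred,
        proba=proba,
        priors=priors,
        config=config,
    )
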