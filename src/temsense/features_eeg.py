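"""EEG asymmetry and correlation features over symmetric electrode pairs.

For each hemispherically symmetric electrode pair — frontal (AF7, AF8)
and temporal (TP9, TP10) — and each of the five canonical bands, three
features summarize how band power is distributed across hemispheres:

* RASM — rational asymmetry, the right/left band-power ratio;
* DASM — differential asymmetry, right minus left band power;
* C    — Pearson correlation between the right and left windowed
  band-power series.

RASM and DASM operate on epoch-mean band powers (scalars); C operates
on the sliding-window band-power time course, so it captures co-waxing
of hemispheric rhythms rather than their mean levels.  Frontal alpha
asymmetry in particular is a classical valence marker, which is why
these 2 pairs x 5 bands x 3 features = 30 values carry the EEG share of
the emotion classifier's input.
"""

from __future__ import annotations

import numpy as np

from .preprocess import DEFAULT_BANDS, band_power, windowed_band_power
from .synthgen import SessionRecording

__all__ = [
    "ELECTRODE_PAIRS",
    "EEG_FEATURE_NAMES",
    "rasm",
    "dasm",
    "band_correlation",
    "extract_eeg_features",
]

#: (region, left channel, right channel); 10-20 convention: odd = left.
ELECTRODE_PAIRS: tuple[tuple[str, str, str], ...] = (
    ("frontal", "AF7", "AF8"),
    ("temporal", "TP9", "TP10"),
)

_FEATURE_KINDS = ("rasm", "dasm", "corr")

#: Canonical 30-name order: pair-major, band-minor, feature-minor.
EEG_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{region}_{band.name}_{kind}"
    for region, _, _ in ELECTRODE_PAIRS
    for band in DEFAULT_BANDS
    for kind in _FEATURE_KINDS
)


def rasm(p_right: float, p_left: float) -> float:
    """Rational asymmetry: right/left band-power ratio."""
    if p_left <= 0:
        raise ValueError(f"left band power must be positive, got {p_left}")
    if p_right < 0:
        raise ValueError("band powers must be nonnegative")
    return p_right / p_left


def dasm(p_right: float, p_left: float) -> float:
    """Differential asymmetry: right minus left band power."""
    return p_right - p_left


def band_correlation(series_right: np.ndarray, series_left: np.ndarray) -> float:
    """Pearson correlation between the two hemisphere band-power series."""
    r = np.asarray(series_right, dtype=float)
    l = np.asarray(series_left, dtype=float)
    if r.shape != l.shape or r.size < 3:
        raise ValueError("series must be equal-length with at least 3 points")
    if np.std(r) == 0 or np.std(l) == 0:
        raise ValueError("band-power series has zero variance")
    return float(np.corrcoef(r, l)[0, 1])


def extract_eeg_features(
    recording: SessionRecording,
    bands=DEFAULT_BANDS,
    window_s: float = 2.0,
    hop_s: float = 1.0,
) -> dict[str, float]:
    """Compute the 30 EEG features of one session, in canonical order.

    Returns an ordered mapping with keys :data:`EEG_FEATURE_NAMES`
    (for the default bands).
    """
    fs = recording.fs
    out: dict[str, float] = {}
    for region, left, right in ELECTRODE_PAIRS:
        for band in bands:
            p_r = band_power(recording.eeg[right], fs, band)
            p_l = band_power(recording.eeg[left], fs, band)
            series_r = windowed_band_power(recording.eeg[right], fs, band, window_s, hop_s)
            series_l = windowed_band_power(recording.eeg[left], fs, band, window_s, hop_s)
            out[f"{region}_{band.name}_rasm"] = rasm(p_r, p_l)
            out[f"{region}_{band.name}_dasm"] = dasm(p_r, p_l)
            out[f"{region}_{band.name}_corr"] = band_correlation(series_r, series_l)
    return out
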