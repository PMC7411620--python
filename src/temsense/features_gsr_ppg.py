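"""Electrodermal statistics and PPG cardiac features.

GSR is summarized by four time-domain statistics of the conductance
samples — variance, Shannon entropy of the 16-bin value histogram,
kurtosis and skewness — which together capture how strongly and how
irregularly the sympathetic phasic responses perturb the tonic level.

PPG is reduced to heart rate (beats per minute over the record) and
"HRV" defined as the mean inter-beat interval in milliseconds, after
detecting systolic pulse peaks on the smoothed, detrended waveform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import savgol_smooth

__all__ = [
    "PeakTrain",
    "gsr_features",
    "detect_pulse_peaks",
    "heart_rate",
    "hrv",
]

GSR_FEATURE_NAMES: tuple[str, ...] = (
    "gsr_variance",
    "gsr_entropy",
    "gsr_kurtosis",
    "gsr_skewness",
)
PPG_FEATURE_NAMES: tuple[str, ...] = ("ppg_hr", "ppg_hrv")

_ENTROPY_BINS = 16
_MIN_PEAK_SEPARATION_S = 0.33


@dataclass(frozen=True)
class PeakTrain:
    """Ascending systolic-peak sample indices of one PPG record."""

    indices: np.ndarray
    fs: float
    duration_s: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices)
        if idx.size and (np.any(np.diff(idx) <= 0) or idx[-1] >= self.duration_s * self.fs):
            raise ValueError("peak indices must be strictly increasing and in range")

    @property
    def times_s(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=float) / self.fs

    def __len__(self) -> int:
        return len(self.indices)


def gsr_features(x: np.ndarray, literal_kurtosis: bool = False) -> dict[str, float]:
    """Variance, histogram entropy, kurtosis and skewness of a GSR record.

    * variance — population second central moment, in microsiemens squared;
    * entropy — Shannon entropy (natural log) of the probabilities of a
      16-bin equal-width histogram over the sample range, so it is
      invariant to affine rescaling of the signal;
    * kurtosis — m4/m2 squared (the conventional, dimensionless form;
      ``literal_kurtosis=True`` selects m4/variance instead);
    * skewness — m3/m2^(3/2).

    A constant record has zero variance and entropy; its kurtosis and
    skewness are undefined and are reported as 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 32:
        raise ValueError(f"need at least 32 samples, got {x.size}")
    m2 = float(np.var(x))
    counts, _ = np.histogram(x, bins=_ENTROPY_BINS)
    p = counts[counts > 0] / x.size
    entropy = float(-np.sum(p * np.log(p)))
    if m2 == 0:
        warnings.warn("constant GSR record: kurtosis/skewness undefined, reported as 0")
        return {
            "gsr_variance": 0.0,
            "gsr_entropy": 0.0,
            "gsr_kurtosis": 0.0,
            "gsr_skewness": 0.0,
        }
    centered = x - x.mean()
    m3 = float(np.mean(centered**3))
    m4 = float(np.mean(centered**4))
    kurtosis = m4 / m2 if literal_kurtosis else m4 / m2**2
    return {
        "gsr_variance": m2,
        "gsr_entropy": entropy,
        "gsr_kurtosis": kurtosis,
        "gsr_skewness": m3 / m2**1.5,
    }


def detect_pulse_peaks(ppg: np.ndarray, fs: float) -> PeakTrain:
    """Locate systolic pulse peaks in a PPG record.

    The waveform is Savitzky-Golay smoothed and linearly detrended, then
    local maxima with prominence of at least half the signal's standard
    deviation and a refractory separation of 0.33 s (supporting rates up
    to ~180 bpm) are kept.  An empty train is returned when nothing
    crosses the prominence floor (e.g. a flat record).
    """
    ppg = np.asarray(ppg, dtype=float)
    if ppg.size < 5 * fs:
        raise ValueError("need at least 5 s of PPG signal")
    x = sps.detrend(savgol_smooth(ppg))
    sd = x.std()
    if sd == 0:
        return PeakTrain(np.array([], dtype=int), fs, ppg.size / fs)
    peaks, _ = sps.find_peaks(
        x, prominence=0.5 * sd, distance=max(1, int(_MIN_PEAK_SEPARATION_S * fs))
    )
    return PeakTrain(peaks, fs, ppg.size / fs)


def heart_rate(peaks: PeakTrain) -> float:
    """Beats per minute: (n_beats - 1) / elapsed time between first and last."""
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks to estimate heart rate")
    t = peaks.times_s
    return (len(peaks) - 1) / (t[-1] - t[0]) * 60.0


def hrv(peaks: PeakTrain) -> float:
    """Mean inter-beat interval in milliseconds."""
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks to estimate HRV")
    return float(np.mean(np.diff(peaks.times_s)) * 1000.0)


def sdnn(peaks: PeakTrain) -> float:
    """Standard deviation of inter-beat intervals (ms); secondary output,
    not part of the 36-feature vector."""
    if len(peaks) < 3:
        raise ValueError("need at least 3 peaks to estimate SDNN")
    return float(np.std(np.diff(peaks.times_s), ddof=1) * 1000.0)
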