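"""Signal smoothing and EEG band-power estimation.

All three modalities (EEG, GSR, PPG) are smoothed with a Savitzky-Golay
filter, which fits a local least-squares polynomial in a sliding window
and therefore smooths sensor noise without distorting slow signal
tendency.  EEG spectral content is summarized as mean power in the five
canonical bands (delta through gamma), estimated with a Welch
averaged-periodogram PSD integrated over the band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "savgol_smooth",
    "band_power",
    "windowed_band_power",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named EEG frequency band ``[low_hz, high_hz]``."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"invalid band edges ({self.low_hz}, {self.high_hz})")


#: Conventional EEG band edges (Hz), ordered low to high.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)

BAND_ORDER: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


def savgol_smooth(x: np.ndarray, window_len: int = 31, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing with same-length output.

    Boundaries are handled by polynomial-fit extrapolation (scipy's
    ``mode='interp'``), so polynomials up to ``polyorder`` are
    reproduced exactly over the whole record, edges included.
    """
    x = np.asarray(x, dtype=float)
    if window_len % 2 == 0:
        raise ValueError(f"window_len must be odd, got {window_len}")
    if window_len <= polyorder:
        raise ValueError("window_len must exceed polyorder")
    if x.size < window_len:
        raise ValueError(f"signal length {x.size} < window {window_len}")
    return sps.savgol_filter(x, window_len, polyorder, mode="interp")


def _check_band(band: BandDefinition, fs: float) -> None:
    if band.high_hz > fs / 2:
        raise ValueError(f"band {band.name} exceeds Nyquist {fs / 2} Hz")


def band_power(
    x: np.ndarray, fs: float, band: BandDefinition, segment_s: float = 2.0
) -> float:
    """Mean power of ``x`` inside ``band``, via Welch PSD integration.

    The PSD is estimated with Hann-windowed segments of ``segment_s``
    seconds at 50% overlap and integrated (trapezoid) over
    ``[low_hz, high_hz]``.  For a zero-mean signal the integral of the
    full PSD equals the variance, so the result is in squared signal
    units (microvolts squared for EEG).
    """
    x = np.asarray(x, dtype=float)
    _check_band(band, fs)
    nperseg = int(round(segment_s * fs))
    if x.size < nperseg:
        raise ValueError(f"signal length {x.size} < one {segment_s} s segment")
    freqs, psd = sps.welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2, window="hann")
    mask = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    return float(np.trapezoid(psd[mask], freqs[mask]))


def windowed_band_power(
    x: np.ndarray,
    fs: float,
    band: BandDefinition,
    window_s: float = 2.0,
    hop_s: float = 1.0,
) -> np.ndarray:
    """Band power in sliding windows: one value per window position.

    Yields ``floor((n_samples - window) / hop) + 1`` values; each is the
    Welch band power of one window (a single segment when the window is
    no longer than the Welch segment length).
    """
    x = np.asarray(x, dtype=float)
    win = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    if win > x.size:
        raise ValueError(f"window {window_s} s exceeds signal duration")
    if hop < 1:
        raise ValueError("hop must be at least one sample")
    n_windows = (x.size - win) // hop + 1
    out = np.empty(n_windows)
    for i in range(n_windows):
        seg = x[i * hop : i * hop + win]
        out[i] = band_power(seg, fs, band, segment_s=min(window_s, 2.0))
    return out
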