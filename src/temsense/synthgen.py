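"""Seeded synthetic multimodal physiology sessions with known ground truth.

The study design this generator emulates: 21 participants each watch 4
tactile-enhanced multimedia clips (58, 35, 21 and 55 s) while a 4-channel
consumer EEG headband (TP9, AF7, AF8, TP10), a skin-conductance (GSR)
sensor and an ear-lobe photoplethysmograph (PPG) record at 256 Hz, and
each session receives an integer SAM valence/arousal rating on a 1-9
scale.  No real recordings are available, so each emotion condition is
given a distinct, physiologically motivated generative signature:

* **EEG** - per-band band-limited noise (delta..gamma, filtered white
  noise scaled to a target band power).  Valence modulates frontal and
  temporal alpha asymmetry: the right-hemisphere alpha power is
  ``alpha_asymmetry_gain`` times the left, with gain > 1 for positive
  valence and < 1 for negative.
* **GSR** - slow tonic level plus phasic skin-conductance responses:
  Poisson-timed events (rate set by arousal) convolved with a
  bi-exponential kernel (0.75 s rise, 2.0 s decay), in microsiemens.
* **PPG** - quasi-periodic pulse train at an emotion-dependent mean
  heart rate with Gaussian inter-beat jitter, plus baseline wander and
  white noise.

Everything is driven by integer seeds: the same configuration and master
seed regenerate the dataset bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .labeling import EMOTIONS, SAMRating, label_emotion
from .preprocess import DEFAULT_BANDS

__all__ = [
    "EmotionParams",
    "SynthConfig",
    "SessionRecording",
    "GroundTruth",
    "generate_session",
    "generate_dataset",
]

EEG_CHANNELS: tuple[str, ...] = ("TP9", "AF7", "AF8", "TP10")
LEFT_CHANNELS = frozenset({"TP9", "AF7"})  # odd 10-20 labels = left hemisphere

#: Target mean band power (microvolts squared) for each canonical band,
#: before asymmetry scaling; a conventional 1/f-like profile.
BASE_BAND_POWER_UV2: dict[str, float] = {
    "delta": 40.0,
    "theta": 20.0,
    "alpha": 15.0,
    "beta": 8.0,
    "gamma": 3.0,
}

_SCR_RISE_S = 0.75
_SCR_DECAY_S = 2.0
_PULSE_WIDTH_S = 0.10  # Gaussian systolic bump width (sd)


@dataclass(frozen=True)
class EmotionParams:
    """Generative parameters for one emotion condition.

    ``valence_mean``/``arousal_mean`` are SAM-scale centers (1-9);
    ``alpha_asymmetry_gain`` is the right/left alpha power ratio;
    ``scr_rate`` in events/min; ``hr_mean`` in bpm; ``ibi_jitter_sd``
    in ms.
    """

    valence_mean: float
    arousal_mean: float
    alpha_asymmetry_gain: float
    scr_rate: float
    hr_mean: float
    ibi_jitter_sd: float

    def __post_init__(self) -> None:
        if not 1 <= self.valence_mean <= 9 or not 1 <= self.arousal_mean <= 9:
            raise ValueError("valence/arousal means must lie in [1, 9]")
        if not 30 < self.hr_mean < 200:
            raise ValueError(f"hr_mean {self.hr_mean} outside (30, 200) bpm")
        if self.alpha_asymmetry_gain <= 0 or self.scr_rate < 0 or self.ibi_jitter_sd < 0:
            raise ValueError("gains, rates and jitter must be nonnegative")


#: Default per-emotion conditions.  Valence sets the alpha asymmetry
#: direction (gain 1.6 vs 1/1.6); arousal sets the SCR rate (8 vs 3
#: events/min) and shifts heart rate up; inter-beat jitter is larger in
#: low-arousal states (more vagal variability at rest).
DEFAULT_EMOTION_PARAMS: dict[str, EmotionParams] = {
    "happy": EmotionParams(7.0, 7.0, 1.6, 8.0, 78.0, 30.0),
    "angry": EmotionParams(3.0, 7.0, 0.625, 8.0, 82.0, 22.0),
    "sad": EmotionParams(3.0, 3.0, 0.625, 3.0, 64.0, 55.0),
    "relaxed": EmotionParams(7.0, 3.0, 1.6, 3.0, 68.0, 45.0),
}

#: Class counts of the emulated study: happy 40, angry 13, sad 22,
#: relaxed 9 over the 84 sessions.
DEFAULT_EMOTION_COUNTS: dict[str, int] = {
    "happy": 40,
    "angry": 13,
    "sad": 22,
    "relaxed": 9,
}


@dataclass
class SynthConfig:
    """Configuration for the synthetic-session generator."""

    n_participants: int = 21
    clip_durations_s: tuple[float, ...] = (58.0, 35.0, 21.0, 55.0)
    fs: float = 256.0
    emotion_params: dict[str, EmotionParams] = field(
        default_factory=lambda: dict(DEFAULT_EMOTION_PARAMS)
    )
    #: "fixed": deal exactly `emotion_counts` labels over the sessions;
    #: "weights": draw i.i.d. with probabilities `emotion_weights`.
    assignment: str = "fixed"
    emotion_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_EMOTION_COUNTS)
    )
    emotion_weights: dict[str, float] | None = None
    rating_sd: float = 1.0
    # measurement noise, per modality (signal units)
    eeg_noise_uv: float = 2.0
    gsr_noise_us: float = 0.01
    ppg_noise: float = 0.05
    # between-participant variability
    participant_hr_sd: float = 3.0
    participant_gain_log_sd: float = 0.08
    master_seed: int = 20200721

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if any(d <= 0 for d in self.clip_durations_s):
            raise ValueError("all clip durations must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.assignment not in ("fixed", "weights"):
            raise ValueError(f"unknown assignment mode {self.assignment!r}")
        if set(self.emotion_params) != set(EMOTIONS):
            raise ValueError("emotion_params must cover exactly the four emotions")
        if self.assignment == "weights":
            if self.emotion_weights is None:
                raise ValueError("weights assignment requires emotion_weights")
            total = sum(self.emotion_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"emotion weights must sum to 1, got {total}")

    @property
    def n_clips(self) -> int:
        return len(self.clip_durations_s)

    @property
    def n_sessions(self) -> int:
        return self.n_participants * self.n_clips


@dataclass
class SessionRecording:
    """One participant x clip multichannel recording at a common rate."""

    participant_id: str
    clip_id: str
    fs: float
    eeg: dict[str, np.ndarray]  # TP9, AF7, AF8, TP10 in microvolts
    gsr: np.ndarray  # microsiemens
    ppg: np.ndarray  # arbitrary units

    def __post_init__(self) -> None:
        if tuple(self.eeg) != EEG_CHANNELS:
            raise ValueError(f"EEG channels must be exactly {EEG_CHANNELS}")
        lengths = {len(v) for v in self.eeg.values()} | {len(self.gsr), len(self.ppg)}
        if len(lengths) != 1:
            raise ValueError("all channels must have the same length")

    @property
    def n_samples(self) -> int:
        return len(self.gsr)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def key(self) -> tuple[str, str]:
        return (self.participant_id, self.clip_id)


@dataclass(frozen=True)
class GroundTruth:
    """True generative condition for one emitted session."""

    participant_id: str
    clip_id: str
    emotion: str
    rating: SAMRating
    hr_mean: float
    scr_rate: float
    alpha_asymmetry_gain: float
    ibi_jitter_sd: float
    n_scr_events: int
    seed: int


def _band_noise(rng: np.random.Generator, n: int, fs: float, low: float, high: float,
                power: float) -> np.ndarray:
    """White noise band-passed to [low, high] Hz and scaled to exact variance."""
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n + int(4 * fs)))[int(2 * fs):][:n]
    sd = x.std()
    if sd == 0:
        return np.zeros(n)
    return x * (np.sqrt(power) / sd)


def _synth_eeg(rng: np.random.Generator, n: int, fs: float, alpha_gain: float,
               noise_sd: float) -> dict[str, np.ndarray]:
    channels: dict[str, np.ndarray] = {}
    for name in EEG_CHANNELS:
        parts = []
        for band in DEFAULT_BANDS:
            power = BASE_BAND_POWER_UV2[band.name]
            if band.name == "alpha" and name not in LEFT_CHANNELS:
                power *= alpha_gain
            parts.append(_band_noise(rng, n, fs, band.low_hz, band.high_hz, power))
        x = np.sum(parts, axis=0)
        if noise_sd > 0:
            x = x + rng.normal(0.0, noise_sd, n)
        channels[name] = x
    return channels


def _scr_kernel(fs: float) -> np.ndarray:
    """Bi-exponential SCR shape (0.75 s rise, 2.0 s decay), unit peak."""
    t = np.arange(0, 10.0, 1.0 / fs)
    k = np.exp(-t / _SCR_DECAY_S) - np.exp(-t / _SCR_RISE_S)
    return k / k.max()


def _synth_gsr(rng: np.random.Generator, n: int, fs: float, scr_rate_per_min: float,
               noise_sd: float) -> tuple[np.ndarray, int]:
    duration = n / fs
    t = np.arange(n) / fs
    tonic = 2.0 + 0.2 * np.sin(2 * np.pi * 0.01 * t + rng.uniform(0, 2 * np.pi))
    tonic = tonic + rng.normal(0, 0.05) * t / max(duration, 1.0)  # slow drift
    n_events = rng.poisson(scr_rate_per_min * duration / 60.0)
    phasic = np.zeros(n)
    if n_events:
        impulses = np.zeros(n)
        onsets = np.sort(rng.uniform(0, duration, n_events))
        amplitudes = rng.lognormal(mean=np.log(0.3), sigma=0.3, size=n_events)
        for onset, amp in zip(onsets, amplitudes):
            impulses[int(onset * fs)] += amp
        phasic = sps.fftconvolve(impulses, _scr_kernel(fs))[:n]
    x = tonic + phasic
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, n)
    return x, int(n_events)


def _synth_ppg(rng: np.random.Generator, n: int, fs: float, hr_mean: float,
               ibi_jitter_ms: float, noise_sd: float) -> np.ndarray:
    duration = n / fs
    ibi = 60.0 / hr_mean
    beats = []
    tk = rng.uniform(0, ibi)
    while tk < duration + ibi:
        beats.append(tk)
        tk += ibi + rng.normal(0.0, ibi_jitter_ms / 1000.0)
    t = np.arange(n) / fs
    x = np.zeros(n)
    for bt in beats:
        lo = max(0, int((bt - 4 * _PULSE_WIDTH_S) * fs))
        hi = min(n, int((bt + 4 * _PULSE_WIDTH_S) * fs) + 1)
        if lo < hi:
            x[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - bt) / _PULSE_WIDTH_S) ** 2)
    x = x + 0.2 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, n)
    return x


def _sample_rating(rng: np.random.Generator, params: EmotionParams, emotion: str,
                   rating_sd: float) -> SAMRating:
    """Draw an integer SAM rating consistent with the emotion's quadrant.

    Normal draws around the condition's (valence, arousal) center are
    rounded and clipped to [1, 9]; draws that land on the midpoint 5 or
    in the wrong quadrant are rejected and redrawn, so the emitted
    rating always labels back to its own condition.
    """
    for _ in range(1000):
        v = int(np.clip(np.round(rng.normal(params.valence_mean, rating_sd)), 1, 9))
        a = int(np.clip(np.round(rng.normal(params.arousal_mean, rating_sd)), 1, 9))
        if v == 5 or a == 5:
            continue
        rating = SAMRating(v, a)
        if label_emotion(rating) == emotion:
            return rating
    # Rejection failing 1000 times means the configured center is far
    # outside its quadrant; fall back to the rounded center.
    return SAMRating(int(round(params.valence_mean)), int(round(params.arousal_mean)))


def generate_session(
    config: SynthConfig,
    participant: int,
    clip: int,
    emotion: str,
    seed: int,
    param_overrides: dict[str, float] | None = None,
) -> tuple[SessionRecording, GroundTruth]:
    """Generate one session for a participant/clip/emotion triple.

    ``param_overrides`` replaces fields of the emotion's
    :class:`EmotionParams` (used by :func:`generate_dataset` to inject
    between-participant variability).  Identical arguments always
    reproduce bit-identical output.
    """
    if emotion not in EMOTIONS:
        raise ValueError(f"unknown emotion {emotion!r}")
    duration = config.clip_durations_s[clip]
    if duration <= 0:
        raise ValueError("clip duration must be positive")
    params = config.emotion_params[emotion]
    if param_overrides:
        params = dataclasses.replace(params, **param_overrides)
    n = int(round(duration * config.fs))
    rng = np.random.default_rng(seed)

    eeg = _synth_eeg(rng, n, config.fs, params.alpha_asymmetry_gain, config.eeg_noise_uv)
    gsr, n_scr = _synth_gsr(rng, n, config.fs, params.scr_rate, config.gsr_noise_us)
    ppg = _synth_ppg(rng, n, config.fs, params.hr_mean, params.ibi_jitter_sd,
                     config.ppg_noise)
    rating = _sample_rating(rng, params, emotion, config.rating_sd)

    recording = SessionRecording(
        participant_id=f"P{participant + 1:02d}",
        clip_id=f"clip{clip + 1}",
        fs=config.fs,
        eeg=eeg,
        gsr=gsr,
        ppg=ppg,
    )
    truth = GroundTruth(
        participant_id=recording.participant_id,
        clip_id=recording.clip_id,
        emotion=emotion,
        rating=rating,
        hr_mean=params.hr_mean,
        scr_rate=params.scr_rate,
        alpha_asymmetry_gain=params.alpha_asymmetry_gain,
        ibi_jitter_sd=params.ibi_jitter_sd,
        n_scr_events=n_scr,
        seed=seed,
    )
    return recording, truth


def _assign_emotions(config: SynthConfig, rng: np.random.Generator) -> list[str]:
    n = config.n_sessions
    if config.assignment == "fixed":
        counts = dict(config.emotion_counts)
        if sum(counts.values()) != n:
            raise ValueError(
                f"emotion_counts sum {sum(counts.values())} != n_sessions {n}"
            )
        pool = [e for e in EMOTIONS for _ in range(counts[e])]
        rng.shuffle(pool)
        return pool
    weights = [config.emotion_weights[e] for e in EMOTIONS]  # type: ignore[index]
    return list(rng.choice(EMOTIONS, size=n, p=weights))


def generate_dataset(
    config: SynthConfig | None = None,
) -> tuple[list[SessionRecording], list[GroundTruth], dict]:
    """Generate the full synthetic dataset plus a reproducibility manifest.

    Sessions are ordered participant-major, clip-minor; the default
    configuration yields 21 x 4 = 84 sessions with the study's fixed
    class split.  Between-participant variability is injected as a
    participant-level heart-rate offset and a log-normal multiplier on
    the alpha asymmetry gain.
    """
    if config is None:
        config = SynthConfig()
    master = np.random.default_rng(config.master_seed)
    emotions = _assign_emotions(config, master)
    seeds = master.integers(0, 2**31, size=config.n_sessions)
    hr_offsets = master.normal(0.0, config.participant_hr_sd, config.n_participants)
    gain_mults = np.exp(
        master.normal(0.0, config.participant_gain_log_sd, config.n_participants)
    )

    sessions: list[SessionRecording] = []
    truths: list[GroundTruth] = []
    rows = []
    for p in range(config.n_participants):
        for c in range(config.n_clips):
            i = p * config.n_clips + c
            emotion = emotions[i]
            base = config.emotion_params[emotion]
            overrides = {
                "hr_mean": float(np.clip(base.hr_mean + hr_offsets[p], 31, 199)),
                "alpha_asymmetry_gain": float(
                    base.alpha_asymmetry_gain * gain_mults[p]
                ),
            }
            rec, truth = generate_session(
                config, p, c, emotion, int(seeds[i]), param_overrides=overrides
            )
            sessions.append(rec)
            truths.append(truth)
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "clip_id": rec.clip_id,
                    "emotion": emotion,
                    "valence": truth.rating.valence,
                    "arousal": truth.rating.arousal,
                    "seed": truth.seed,
                    "hr_mean": truth.hr_mean,
                    "scr_rate": truth.scr_rate,
                    "alpha_asymmetry_gain": truth.alpha_asymmetry_gain,
                    "ibi_jitter_sd": truth.ibi_jitter_sd,
                    "n_scr_events": truth.n_scr_events,
                    "duration_s": rec.duration_s,
                }
            )
    manifest = {
        "master_seed": config.master_seed,
        "n_participants": config.n_participants,
        "clip_durations_s": list(config.clip_durations_s),
        "fs": config.fs,
        "assignment": config.assignment,
        "sessions": rows,
    }
    return sessions, truths, manifest
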