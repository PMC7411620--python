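# Methods

## Problem and scope

The pipeline recognizes four Russell-quadrant emotions from three
physiological modalities recorded while a viewer experiences
tactile-enhanced multimedia (video synchronized with hot/cold airflow).
The emulated acquisition: 21 participants × 4 clips (58, 35, 21, 55 s),
a 4-electrode consumer EEG headband (TP9, AF7, AF8, TP10 per the 10–20
system; odd labels = left hemisphere), one GSR channel (µS) and one
ear-lobe PPG channel, all at 256 Hz, plus one integer SAM
valence/arousal rating (1–9) per session. The original recordings were
never released, so a synthetic generator defines the test bed; the
study's published confusion matrices are shipped as inputs so its
reported metrics are independently recomputable.

## Labeling

Quadrant assignment with midpoint 5: a score strictly above 5 is
"high". Exact 5s go to the low side — a documented policy choice; the
generator never emits 5s, so no downstream count depends on it.
Canonical class order everywhere is (relaxed, sad, happy, angry).

## Synthetic generator

Each emotion condition plants a distinct, physiologically motivated
signature; the defaults are the study conditions the package is tested
under:

| condition | valence, arousal center | α gain (R/L) | SCR rate (min⁻¹) | HR (bpm) | IBI jitter (ms) |
|-----------|------------------------|--------------|------------------|----------|-----------------|
| happy     | 7, 7                   | 1.6          | 8                | 78       | 30              |
| angry     | 3, 7                   | 0.625        | 8                | 82       | 22              |
| sad       | 3, 3                   | 0.625        | 3                | 64       | 55              |
| relaxed   | 7, 3                   | 1.6          | 3                | 68       | 45              |

- **EEG**: each channel is a sum of band-limited white noise, one
  component per canonical band (δ 1–4, θ 4–8, α 8–13, β 13–30,
  γ 30–45 Hz; 4th-order Butterworth, zero-phase), each scaled to an
  exact target variance (40/20/15/8/3 µV²; a conventional 1/f-like
  profile). Right-hemisphere alpha variance is multiplied by the
  condition's asymmetry gain, so valence-dependent frontal/temporal
  alpha asymmetry is the planted EEG effect, recoverable by the RASM
  feature. Per-band synthesis gives controllable per-band power ground
  truth for the feature tests. Broadband measurement noise (sd 2 µV)
  is added on top.
- **GSR**: tonic level ~2 µS with slow sinusoidal drift, plus phasic
  skin-conductance responses — Poisson-timed impulses (rate set by
  arousal) with log-normal amplitudes (~0.3 µS) convolved with a
  bi-exponential kernel (0.75 s rise, 2.0 s decay). The drawn event
  count is recorded in the ground truth for rate-recovery tests.
- **PPG**: Gaussian systolic bumps (sd 0.10 s, unit amplitude) at beat
  times generated by a jittered renewal process (mean interval 60/HR,
  Gaussian jitter), plus 0.25 Hz baseline wander (amplitude 0.2) and
  white noise.
- **Ratings**: integer normal draws (sd 1) around the condition's
  center, clipped to [1, 9], rejected and redrawn if on the midpoint or
  in the wrong quadrant — label consistency is guaranteed at generation
  time.
- **Assignment**: "fixed" mode deals exactly the study's 40/13/22/9
  class counts across the 84 sessions (seeded shuffle); an i.i.d.
  weights mode exists for small ad-hoc datasets.
- **Between-participant variability**: a per-participant HR offset
  (sd 3 bpm) and a log-normal multiplier (log-sd 0.08) on the alpha
  gain, so sessions from one participant are correlated the way repeat
  measurements are.
- **Determinism**: a master seed yields per-session integer seeds
  (recorded in the manifest); identical configuration regenerates the
  dataset bit-identically.

What the generator does *not* emulate: volume-conducted source mixing,
eye-blink/EMG artifacts, nonstationary tonic EDA trends, PPG waveform
morphology (dicrotic notch), or any clip-content-driven temporal
structure. Passing tests therefore demonstrate that the pipeline
recovers planted effects of realistic magnitude from signals with the
right units, rates and spectra — not that the classifier would reach
the same accuracy on real recordings.

## Pre-processing and features

- Savitzky–Golay smoothing: window 31 samples (~0.12 s at 256 Hz),
  polynomial order 3, applied to all modalities; boundary handling by
  polynomial extrapolation (same-length output). Chosen to suppress
  sensor noise while leaving systolic peaks intact; configurable.
- Band power: Welch averaged periodogram, 2 s Hann segments, 50 %
  overlap, trapezoid-integrated over the band. The analysis epoch is
  the whole clip.
- The correlation feature C_b uses windowed band-power series (2 s
  window, 1 s hop) per hemisphere; RASM/DASM use epoch-mean powers.
- GSR kurtosis is the standard dimensionless m₄/m₂² (a
  `literal_kurtosis` flag provides the dimensional m₄/V variant);
  skewness is m₃/m₂^{3/2}. Entropy uses a 16-bin equal-width histogram
  over the sample range with natural log and 0·log 0 = 0, making it
  invariant to affine rescaling.
- "R-peaks" on PPG are read as systolic pulse peaks: maxima of the
  smoothed, detrended waveform with prominence ≥ 0.5 × sd and ≥ 0.33 s
  separation (supports up to ~180 bpm). HRV is the mean inter-beat
  interval (ms), matching the source design; SDNN is available as a
  secondary output but excluded from the 36-feature vector.

## Classification and evaluation

- KNN with k = 3 by default (k was not fixed by the source design; the
  analysis driver reports sensitivity over k ∈ {1, 3, 5, 7}), Euclidean
  distance on z-scored features. Scaling is essential: raw columns mix
  µV², unitless ratios and ms, and unscaled distances would be
  dominated by HRV.
- Cross-validation: seeded stratified 10-fold assignment by dealing
  each class's shuffled members round-robin across folds (fold sizes
  differ by at most one; works for the 9-member relaxed class, which
  standard stratified splitters reject at 10 folds). Normalization
  statistics are fit on each training fold only.
- Probability vectors are neighbor-vote fractions; vote ties go to the
  nearest single neighbor's class (deterministic).
- MAE/RMSE/RAE/RRSE follow the per-class probability-vs-0/1-indicator
  convention, averaged over all N × C entries, with the training-fold
  class priors as the reference predictor for the relative forms.
- Published-matrix caveat: of the four shipped confusion matrices, the
  GSR, PPG and fusion ones are printed transposed relative to the EEG
  one (their column sums match the 9/22/40/13 class counts). Accuracy
  and kappa are transpose-invariant and are reported for all four;
  per-class rates are only meaningful for the row-consistent EEG
  matrix. Two of that matrix's printed specificities (relaxed, happy)
  differ by ~0.5 points from direct recomputation and are not used as
  checks.

## Numerical and degenerate-input policy

Constant GSR records report V = E = 0 and flag K, S as undefined
(emitted as 0 with a warning). A zero-variance band-power series makes
C_b undefined and raises. RASM requires strictly positive left power.
Fewer than two detected pulse peaks raises for HR/HRV. Zero-variance
feature columns are given unit scale during z-scoring so they
contribute no distance.

## Problem sizes

The default test suite and the acceptance script both regenerate the
full 84-session dataset (10–60 s epochs at 256 Hz) and extract all
features in well under a minute on one CPU; property tests use 30–120 s
single-channel signals where spectral estimates need that length.
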