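# Methods

## Problem

Estimating a horse's locomotion speed from body-mounted inertial measurement
units (IMUs) rather than GPS: GPS needs sky view and IMU double-integration
drifts, but the *pattern* of acceleration and angular velocity carries speed
information that a regression model can decode. The package implements the
whole chain — signal generation, preprocessing, feature engineering, feature
selection, model comparison and a stride-frequency baseline — on synthetic
recordings with known ground truth, so every stage is testable end to end
without access to animal data.

## Synthetic gait recordings

Seven IMUs (poll, withers, sacrum, and the four cannon bones: RF, LF, RH,
LH) each stream tri-axial acceleration (m/s²) and angular velocity (deg/s)
at 200 Hz, beside a 5 Hz ground-truth speed series, mimicking a
Doppler-GPS-equipped gait-analysis setup. Five gaits are modelled with the
speed distributions measured in the study population the package emulates:

| gait   | mean ± SD (m/s) | stride f(v) = a + b·v (Hz) |
|--------|-----------------|-----------------------------|
| walk   | 1.70 ± 0.17     | 0.55 + 0.15·v               |
| trot   | 3.30 ± 0.23     | 0.80 + 0.18·v               |
| tölt   | 3.90 ± 0.23     | 0.85 + 0.19·v               |
| canter | 4.95 ± 0.43     | 0.90 + 0.18·v               |
| pace   | 7.52 ± 1.43     | 1.00 + 0.15·v               |

The stride coefficients are simulator choices (no published signal model
exists for this setup): they span ≈ 0.8–2.2 Hz over the gait speed range, a
plausible equine stride-rate band, with b > 0 so stride frequency rises
with speed.

Within a segment, speed follows a mean-reverting (Ornstein–Uhlenbeck) walk
at 5 Hz (reversion rate θ = 0.5 s⁻¹, stationary SD = the per-gait SD),
clipped at 0.05 m/s and held piecewise constant at 200 Hz. Each channel is
a sum of the first three harmonics of the stride frequency, with phase
accumulated from the instantaneous f(v(t)), scaled by an energy–speed
coupling (1 + c·v) with c = 0.15, plus white Gaussian noise (0.3 m/s² acc,
1.5 deg/s gyr).

Channel informativeness is deliberately structured. The primary oscillation
channel of each sensor — limb gyr_z (protraction/retraction) and upper-body
acc_z (vertical displacement) — carries the largest fundamental amplitude,
the full speed coupling, and low between-subject amplitude variability
(relative SD 0.05). Secondary channels get 0.3× the coupling and 2.5× the
subject variability: they reflect individual movement style more than
speed, so a subject-grouped selector learns to prefer the primary channels.
The poll is idiosyncratic on every channel (3× subject variability, c =
0.05, small amplitudes near the noise floor), making it the least
informative sensor. Per-subject amplitude factors and phase offsets are
drawn once per subject; limbs carry fixed phase lags approximating footfall
sequencing.

What the generator does **not** emulate: impact transients at hoof-on
(signals are band-limited harmonic stacks), rider effects, gait
transitions, sensor misalignment or clock drift, and any lameness
asymmetry. Passing tests therefore demonstrate that the pipeline recovers
speed when the assumed signal structure holds — not field performance on
real horses.

## Preprocessing

Channels are low-pass filtered (4th-order Butterworth, 30 Hz cut-off)
before windowing. Filtering is applied forward–backward (zero phase) so
window centers stay aligned with speed timestamps; the effective magnitude
response is the single-pass response squared. Windows are 256 samples, one
per speed sample, centered on the nearest IMU sample; at 200/5 Hz
consecutive windows overlap by 216 samples. Windows lacking full support or
straddling a gait boundary are dropped (per-gait evaluation needs
unambiguous labels); edges are dropped, never padded.

## Features

23 features per channel window, 138 per IMU. Time domain (on the filtered,
unwindowed samples): max, min, mean, median, SD (1/(N−1)), 25th/75th
percentiles (linear interpolation between order statistics), kurtosis and
skewness (both 1/N with population σ; kurtosis raw, Gaussian → 3). Zero
variance ⇒ skewness/kurtosis 0, window flagged degenerate.

Frequency domain (after a symmetric Hann taper): spectral energy
Σ|X_k|² over all N bins of the plain DFT; spectral entropy as the Shannon
entropy (natural log) of the normalized one-sided power distribution (bins
0..N/2, 129 bins); and the magnitude and phase angle of DFT coefficients
k = 1..6 (DC excluded — the coefficient index runs 1..6), the phase via
atan2(Σx·sin, Σx·cos). The one-sided entropy convention and the DFT
normalization are pinned by a Parseval test (Σ|X_k|² = N·Σ(w·x)²) and a
brute-force O(N²) DFT oracle at 1e−9 relative tolerance.

Eleven feature sets combine locations: All (7 sensors, 966 features),
Limbs (552), Sac/Wth, Sac/RF, and the seven singletons (138 each).

## Feature selection (SFFS)

Sequential floating forward selection wrapped around a small random forest
(25 trees, depth 10), scored by subject-grouped k-fold CV RMSE (k = 5
default; grouping prevents within-subject leakage). A feature is added only
if it lowers CV RMSE by > 0.01 m/s; after each addition, features float
out while a removal gains > 0.01 m/s. Ties break to the lowest column
index; a cap (default 30) guards runaway loops; an empty selection on pure
noise is legitimate and flagged. Selection runs once per feature set on
pooled data before the outer evaluation (a leakage-free nested mode that
re-selects inside every training fold is available behind
`--nested-selection`). On six-feature problems SFFS is verified to land
within the 0.01 m/s criterion of the exhaustive optimum over all 63
subsets.

## Models and evaluation

Five families: SVM (RBF kernel, standardized inputs), decision tree,
random forest (100 trees, mtry = p/3, the regression-forest convention), boosted trees (least-squares
gradient boosting, depth 3), and Gaussian process regression (RBF + white
kernel, standardized, marginal-likelihood-optimized). GPR fits on a seeded
subsample of at most 800 training rows — the exact fit is cubic in n and
the subsample leaves its accuracy competitive at these problem sizes.

Evaluation is leave-one-subject-out: one fold per subject, predictions
pooled across folds into a single vector before computing MAE, RMSE and
nRMSE = RMSE / mean measured speed (in %), overall and per gait — pooling
first matches the metric definitions over one prediction vector. Default
hyperparameters are fixed (above); an optional inner subject-grouped 3-fold
grid search over small per-family grids (`tune=True`) is implemented but
off by default, since the fixed settings already achieve the recovery
targets at the simulated problem sizes and tuning multiplies the fit count
roughly tenfold. The full grid crosses 11 feature sets × 5 families =
55 cells; failed cells are recorded, not raised.

## Stride-frequency baseline

Hoof-on events of one limb are detected on the band-passed (0.5–8 Hz)
gyr_z: local maxima at least 0.25 s apart exceeding 0.8× a rolling 4 s
amplitude envelope. The threshold fraction and envelope length were
calibrated on seeded white noise so that noise alone triggers < 0.5
events/s on average while clean gait cycles are all retained. Stride
frequency is the reciprocal inter-event interval paired with the
nearest-in-time speed sample; strides spanning a gait boundary are
discarded. Second- and third-degree polynomials speed = P(f) are fit by
least squares and scored in-sample. On synthetic cohorts the polynomial
baseline trails the feature-based models — stride frequency alone ignores
the amplitude information the windows carry — and recovered stride
frequency rises monotonically with speed (Spearman ρ > 0.9 pooled).
A polynomial fit needs at least degree + 2 points; exact-interpolation
designs are rejected rather than reported as zero-error fits.

## Problem sizes

The default test and acceptance runs use scaled-down cohorts chosen to
exercise every stage: 10 subjects × 5 gaits × 21 s (~4,900 windows) for
the main recovery run (random forest + All set, LOSO RMSE ≈ 0.2 m/s,
≈ 89 % better than predicting the training-fold mean), and five 4-subject
cohorts (~12 s per gait) for the majority-of-seeds ordering checks (limb
sets rank gyr_z features first; the poll is the worst sensor; the
polynomial baseline loses to the ML pipeline). The ranking comparison
between families uses a singleton feature set, where boosted-tree and tree
fits stay cheap.

## Known limitations

- The harmonic generator cannot probe features that depend on waveform
  details it lacks (impact transients, stance/swing asymmetry).
- Speed information enters through exactly two mechanisms (stride
  frequency and the amplitude coupling); real signals carry more, and
  also more confounders.
- In-sample polynomial metrics mirror the baseline's original use; they
  are optimistic relative to cross-validated metrics, which is acceptable
  because the baseline still loses to the ML pipeline.
- Per-gait speed distributions overlap little (walk vs pace differ by
  ~6 m/s), so part of the regression task is implicit gait recognition;
  this matches the modelled study design but flatters pooled nRMSE.
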