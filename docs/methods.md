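# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `gaitscore`. The package turns raw three-sensor IMU walking
recordings (waist + both thighs, 100 Hz, 3-axis acceleration and angular
velocity each) into a 0–100 gait-abnormality score.

## 1. Sensor model and preprocessing

Sensors are assumed rigidly attached (waist at the lower lumbar spine,
thighs mid-segment), nominally axis-aligned with the body — the sidecar
metadata declares which raw sensor axis is forward and which is up — and
preceded by a static standing phase of at least 5 s.

**Units.** Input acceleration may be in g or m/s² (metadata flag); internal
units are m/s² with g = 9.81. Calibration offsets are additive per axis.

**Initial orientation.** The mean accelerometer vector over the static
window is the gravity reaction; the initial quaternion is the minimal
rotation taking it onto the global SI axis. The magnitude must be within
20% of g, else the sensor is rejected as non-static. Heading (rotation
about SI) is unobservable from an accelerometer; it is fixed so the
declared forward axis maps onto global AP at t = 0. A forward axis within
numerical tolerance of vertical leaves heading at identity with a warning.

**Orientation tracking.** First-order exponential-map integration of the
body-frame angular velocity: each sample rotates the quaternion by ω·Δt,
renormalizing every step (unit norm is maintained to < 1e-9). At 100 Hz
over ≤ 60 s walks this is accurate to well below the filter's passband
ripple; no magnetometer or complementary filtering is used, so slow yaw
drift is uncorrected — acceptable for 30-stride straight walks, not for
long recordings.

**Filtering.** A 50th-order Hamming windowed-sinc FIR low-pass with 20 Hz
cutoff, applied forward-backward (`filtfilt`) to raw acceleration and
angular velocity before orientation estimation. Zero-phase application
keeps heel-strike peak timing unbiased for segmentation; the effective
magnitude response is the square of the single-pass response (passband
ripple negligible, ≥ 99% amplitude at 5 Hz, ≤ 5% at 35 Hz). Gravity is
*not* subtracted after the frame transform: SI channels carry a +g mean,
and every downstream feature either mean-centers or is location-invariant.

## 2. Stride segmentation

Heel strikes appear as positive peaks in waist AP acceleration. The
detector has three parameters, all exposed in `PipelineConfig`:

- **Step period estimate**: first local peak ≥ 0.2 of the normalized
  biased autocorrelation in the lag band 0.4–2.0 s. No qualifying peak
  means no periodic gait (error). The biased estimator is used here
  because its lag-proportional shrinkage suppresses spurious high-lag
  maxima in short series.
- **Peak detection**: a sample qualifies if it is the maximum of a
  centered window of 0.75 step periods and exceeds mean + 0.2 sd of the
  channel; candidates closer than 0.3 step periods are resolved in favor
  of the higher peak. The threshold in sd units makes detection invariant
  to amplitude scale.
- **Stride formation**: strides span peak *i* → *i+2* with non-overlapping
  pairing (0→2, 2→4, …) anchored at the first event; non-overlap keeps the
  cycles statistically independent for the variance ratio.

Pruning drops the first and last 2 strides (gait initiation/termination
transients), then iteratively removes strides whose duration is more than
twice or less than half the mean of the remaining strides, until stable.
Fewer than 3 surviving strides is an error.

Segmentation can be scored against reference foot-contact events (from
foot-switch hardware or the synthetic generator's ground truth) by greedy
one-to-one nearest matching within a tolerance (default 10 samples =
100 ms); sensitivity = matched/reference, PPV = matched/detected.

## 3. Gait graphs

Each pruned stride is resampled to M = 100 points by linear interpolation
with inclusive endpoint grids (exact on affine signals, identity when the
stride is already 100 samples, no overshoot), then mean-centered per
channel. Centering removes the +g offset on SI channels; Pearson
correlation and the variance ratio are location-adjusted anyway, and the
harmonic/autocorrelation features require centered input. It is exposed as
`center_channels` (default on).

An Average Gait Graph (AGG) is the mean of three consecutive
non-overlapping normalized cycles; four AGGs are built per subject from
the start of the pruned list (fewer, minimum one, with a warning when the
walk is short). The Characteristic Gait Graph (CGG) is the elementwise
mean of healthy-adult AGGs.

Channel selection: for each of the nine channels, the Pearson correlation
of per-subject average gaits over all unordered subject pairs; channels
with mean r ≥ 0.75 are representative. On both published healthy-adult
values and simulated cohorts this selects the six SI/AP channels and
rejects the three ML channels, whose waveforms are subject-idiosyncratic.

## 4. Features

For one AGG (6 × 100) with source cycles and a CGG:

- **P** — sum over the 6 channels of the sample Pearson correlation
  between AGG and CGG; maximum 6. A constant channel yields r = 0 with a
  warning (keeps P finite for pathologically flat signals).
- **V** — sum over channels of the Hershler–Milner variance ratio of the
  n = 3 source cycles: within-phase variance over total variance,
  [ΣᵢΣⱼ(Xᵢⱼ − X̄ᵢ)²/(M(n−1))] / [ΣᵢΣⱼ(Xᵢⱼ − X̄)²/(Mn−1)]. Identical cycles
  → 0; unrelated cycles → ≈ 1 per channel. An all-identical channel
  (zero denominator) returns 0 by convention.
- **N** — sum over channels of first-difference sign changes. Runs of
  exactly equal samples are compressed first, so a plateau counts as at
  most one extremum.
- **H** — waist channels only (SI-W, AP-W): a stride holds two steps, so a
  smooth symmetric gait concentrates energy in even stride harmonics;
  h = ΣC₂,₄,…,₂₀ / ΣC₁,₃,…,₁₉ from the one-sided DFT of the centered
  stride. A vanishing odd sum (< 1e-12) caps h at 1e6 with a warning —
  the ratio is unbounded and a finite sentinel keeps the grey
  normalization usable.
- **S** — waist channels only: the peak of the normalized unbiased
  autocorrelation a(l) = Σx(i)x(i+l)/(M−l), a(l)/a(0), over the step-lag
  band l ∈ [0.3M, 0.7M]. Peak-in-band rather than the fixed lag M/2 is
  used so timing asymmetry (step lag away from 50%) is still credited at
  its true lag; the band is configurable.

  The peak-in-band statistic has a positive noise floor: for white noise
  at M = 100, the mean of As over seeds is ≈ 0.31 (max of ~41 weakly
  correlated estimates whose sd grows toward 1/√(M−l) at the band's upper
  edge). The fixed-lag alternative has floor ≈ 0.11. Tests of the noise
  floor therefore characterize the chosen statistic, not an arbitrary
  constant.

## 5. Grey relational scoring

Training (healthy subjects, 4 AGG feature rows each, features ordered
P, V, N, H, S): Xref = column means of X; rows normalized by the tent map
z = x/Xref if x ≤ Xref else 2 − x/Xref (1 is ideal; values below 0 for
x > 2·Xref are kept — they read as large deviations); R = column means of
Z; minAbs/maxAbs = global extrema of |Z − R|.

Scoring: ξ(j) = (minAbs + γ·maxAbs)/(max(|z(j) − R(j)|, minAbs) + γ·maxAbs)
with γ = 1 and equal weights 0.2; Cᵢ = Σwⱼξᵢ(j); Score = mean(Cᵢ) × 100.

Numerical decisions:

- **ξ clamp.** A test row can deviate from R by less than the training
  minAbs, pushing the textbook coefficient above 1 and the score above
  100. The deviation is floored at minAbs, bounding ξ ≤ 1 and
  Score ∈ [0, 100]; unclamped coefficients are kept in the result for
  audit.
- **Monotonicity.** The score is non-increasing in the *normalized*
  deviation |z − R|. It is not monotone in the raw deviation |x − Xref|:
  the tent map peaks (z = 1) at x = Xref while the score peaks at z = R,
  and R < 1 for any non-degenerate training set, so a small move from
  x = Xref toward the z = R locus raises the score. The property tests
  assert the normalized-deviation form.
- **Degenerate fits.** maxAbs = 0 (all training rows identical) turns ξ
  into an exact-match indicator with a warning; a zero column mean in X is
  an error (the normalization divides by Xref).
- Fewer than 4 test rows are averaged as-is, with a warning.

## 6. Synthetic gait generator

The generator exists because no public recordings match this three-sensor
protocol. It emulates healthy level walking at the waveform level and
injects pathology through three orthogonal dials.

**Template.** One analytic stride per channel (phase t ∈ [0, 1), left
contact at 0), built from harmonic and periodic-bump primitives honoring
healthy waveform landmarks: AP-W peaks at each contact (0 and 50%) with
nearly identical step halves (half-stride-shift correlation ≈ 0.92); SI-W
foot-flat loading peaks just after each contact (6% and 55%, fast rise /
slow decay, slow regions at 25–40% and 75–90%); thigh SI stance bumps at
10% (left) mirrored at 60% (right); thigh AP falling-then-rising (left)
and its half-stride shift (right); ML small and fixed in the template.
Every channel has a gentle slope at the cycle wrap so tiled cycles are
continuous. The two SI-W bumps differ slightly in amplitude (2.0 vs 1.75
m/s²) so the stride spectrum is not purely even and healthy harmonic
ratios stay finite (H ≈ 8–11) instead of saturating the h cap.

**Assembly.** The template is tiled for `n_strides` (default 30) at the
profile's stride frequency (healthy default 0.93 strides/s), preceded by a
5.5 s static standing phase and a quarter-stride ramp-in, and ended with a
taper after the last right contact so no spurious rise toward a
never-occurring next contact remains. Gravity rides on SI. Ground truth:
two events per stride (left at each cycle start, right at mid-cycle),
2·n_strides total.

**Pathology dials** (all relative, seeded):

- `asymmetry` a: waist SI/AP channels are modulated by
  1 + (a/2)·cos(2πt) (left steps scaled up, right steps down) and thigh
  channels by 1 ± a/2 — lowers S (and P).
- `tremor_amp`: 6–15 Hz band-limited noise (FFT-masked white noise) scaled
  to each channel's gait RMS; the band sits below the 20 Hz preprocessing
  cutoff so it survives filtering — raises N, lowers H and P.
- `cycle_noise`: per-cycle waveform jitter (random low-order harmonics and
  amplitude factors at the full dial value) plus stride-duration jitter at
  0.4× the dial value — raises V. The duration share is reduced because
  stride-time variability in impaired gait is small (~5–10% CV) relative
  to waveform variability; a full-value duration CV of 25% would destroy
  the signal's autocorrelation periodicity and make even moderate
  pathology unsegmentable, which contradicts observed practice.

**Sensor embedding.** Global signals are rotated into per-sensor frames
with constant pitch-only orientations (waist 8°, thighs 15°/12°) and
exactly zero angular velocity, plus seeded calibration offsets recorded in
the sidecar. Constant orientation makes the preprocessing round trip exact
and testable; it deliberately omits real thigh rotation during gait, gyro
noise and drift, soft-tissue artifact, and any kinematic model of
pathology beyond waveform perturbation. Passing tests therefore validate
the pipeline's signal processing and scoring logic, not its robustness to
orientation-tracking error on real limbs.

**Severity ladder** (`generate_cohort`): per-severity uniform parameter
ranges, e.g. healthy (stride frequency 0.85–1.0, asymmetry ≤ 0.05, tremor
≤ 0.02, cycle noise 0.01–0.03) down to severe (0.60–0.75 strides/s,
asymmetry 0.45–0.65, tremor 0.25–0.40, cycle noise 0.16–0.25); stride
frequencies span the observed range from healthy self-selected walking to
the slowest severely impaired walkers. The ranges claim ordinal, not
clinical, meaning.

## 7. Problem sizes in tests and the acceptance script

Simulated studies use 30-stride walks, 4 reference healthy adults,
cohorts of 5–8 subjects per severity, 20-subject pathology ladders, and
10–20 seeded replicates for ordering checks — large enough for stable
rank statistics at waveform noise levels, small enough to run the entire
suite in well under a minute of compute per study. All randomness flows
from explicit seeds; identical seeds give bitwise-identical recordings.

## 8. Known limitations

- Heading is metadata-declared, not estimated; a misdeclared forward axis
  rotates AP/ML and degrades P silently.
- No drift correction: long walks or significant gyro bias would need
  complementary/Kalman filtering, out of scope.
- The grey model's score scale depends on the training cohort; scores are
  comparable only against the same fitted model.
- The synthetic severity ladder is an engineering construct; clinical
  validity of score thresholds requires real cohorts.
- Left/right foot labeling from acceleration alone is heuristic (thigh SI
  variance in the first half-stride) and configurable, not validated.
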