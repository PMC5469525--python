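# gaitscore

Acceleration-based gait abnormality scoring from wearable IMUs, for
quantitative motor assessment in conditions such as cerebral palsy.

Clinical gait assessment scales (GMFCS, GMFM) are observer-rated and can be
subjective and slow. `gaitscore` implements an objective alternative built
on three inertial measurement units — one over the lower lumbar spine
(close to the body's center of mass) and one on each mid-thigh — recording
tri-axial acceleration and angular velocity at 100 Hz during a short level
walk of about 30 strides. The output is a single 0–100 score: high for
gait close to the healthy-adult pattern, low for abnormal gait.

## Method

1. **Preprocessing.** Raw streams are offset-calibrated and rotated into a
   common body frame (AP anterior–posterior, SI superior–inferior, ML
   medio-lateral) with quaternions: the initial orientation comes from a
   ≥ 5 s static standing window (gravity onto SI), and gyroscope
   integration tracks orientation during walking. A zero-phase 50th-order
   FIR low-pass at 20 Hz removes out-of-band noise. Gravity is retained on
   the SI channels.
2. **Segmentation.** Each heel strike produces a positive peak in the
   waist AP acceleration (the inverted-pendulum signature of the center of
   mass). Peaks are detected by a window peak search parameterized by the
   autocorrelation-estimated step period; strides run from one peak to the
   second-next. Gait initiation/termination strides and strides outside
   [0.5×, 2×] of the mean duration are pruned.
3. **Gait graphs.** Strides are time-normalized to *M* = 100 points and
   averaged in triples into Average Gait Graphs (AGGs, 4 per subject) over
   the six representative channels (SI-L, AP-L, SI-R, AP-R, SI-W, AP-W —
   the channels reproducible across healthy adults at mean pairwise
   *r* ≥ 0.75; the ML channels do not qualify). The Characteristic Gait
   Graph (CGG) is the mean of healthy-adult AGGs: the standard pattern.
4. **Features.** Each AGG yields five features:
   *P* = Σ channel-wise Pearson *r* against the CGG (max 6);
   *V* = Σ Hershler–Milner variance ratios of the three source cycles
   (0 = perfectly repeatable);
   *N* = Σ extreme-point counts (tremor adds ripple, raising N);
   *H* = Σ waist harmonic ratios (even ÷ odd stride harmonics, 1..20; high =
   smooth, rhythmic);
   *S* = Σ waist step-regularity peaks of the normalized unbiased
   autocorrelation at the step lag (≈ 2 for symmetric gait).
5. **Grey relational scoring.** From healthy training features X (4 AGG rows
   per subject): reference vector Xref = column means; rows normalized by a
   tent map z = x/Xref (x ≤ Xref) or 2 − x/Xref; reference set R = column
   means of Z; minAbs/maxAbs = global extrema of |Z − R|. A test row scores
   ξ(j) = (minAbs + γ·maxAbs)/(|z(j) − R(j)| + γ·maxAbs) with γ = 1, equal
   weights 0.2, C = Σ wⱼξ(j), and Score = mean over the subject's AGG rows
   × 100 (deviations are floored at minAbs so Score ≤ 100).

A seeded synthetic gait generator (`gaitscore.synthetic`) produces walking
trials with known heel-strike ground truth and three pathology dials —
left/right asymmetry, 6–15 Hz tremor, and cycle-to-cycle variability — so
the whole pipeline is testable without recorded data.

## Worked example

```python
import pandas as pd
import gaitscore as gs
from gaitscore import pipeline

cfg = gs.PipelineConfig()

# reference: four simulated healthy adults -> CGG + grey model
healthy = gs.generate_cohort(4, "healthy", seed=1)
cgg = pipeline.build_reference_cgg(healthy, cfg)
train = pd.concat([gs.run_extract(r, cgg, cfg) for r in healthy],
                  ignore_index=True)
model = gs.run_fit(train, cfg)

# an unknown subject with slow cadence, asymmetry and tremor
subject = gs.generate_recording(
    gs.SyntheticGaitProfile(stride_frequency=0.7, asymmetry=0.4,
                            tremor_amp=0.2, cycle_noise=0.1, seed=42),
    subject_id="patient_01")
table = gs.run_extract(subject, cgg, cfg)
print(table.round(2))
print(f"score: {gs.run_assess(table, model)[0].score:.1f}")
```

Output:

```
   subject_id  agg_index     P     V    N     H     S
0  patient_01          0  5.69  2.00  148  4.38  1.71
1  patient_01          1  5.79  1.09  139  5.20  1.74
2  patient_01          2  5.83  1.39  144  5.23  1.75
3  patient_01          3  5.86  1.25  161  5.42  1.74
score: 51.5
```

Against healthy training rows (P ≈ 6.0, V ≈ 0.2, N ≈ 30–40, H ≈ 9–11,
S ≈ 1.94, scores 90–93), the impaired subject shows lower waveform
similarity and smoothness, three times the extreme points, ten times the
cycle-to-cycle variance, reduced step symmetry — and a score of 51.5,
well below the healthy cluster.

The same workflow is available from the shell:

```bash
gaitscore simulate --out rec.csv --meta rec.json --events ev.csv --seed 3
gaitscore segment-eval --recording rec.csv --meta rec.json --events ev.csv
gaitscore extract --recording rec.csv --meta rec.json --cgg cgg.csv --out f.csv
gaitscore fit --features healthy.csv --out model.json
gaitscore assess --features f.csv --model model.json --out report.json
```

## Limitations

Severity levels of the synthetic generator are ordinal engineering choices,
not clinically calibrated; scores on real recordings require a CGG and grey
model fitted to real healthy-adult data. Straight-line level walking only;
no magnetometer fusion or long-walk drift correction. See
`docs/methods.md` for the full model description and design rationale.
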