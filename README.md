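# kneegait

Downstream gait analysis for markerless motion capture, built for clinical
studies of knee osteoarthritis (KOA) compensation. Systems such as OpenCap
turn two smartphone videos into OpenSim outputs — marker trajectories (TRC)
and joint angles (MOT). `kneegait` takes it from there: it detects gait
events, computes spatiotemporal parameters and peak joint angles, compares
patient and control cohorts statistically, and performs phase-wise bootstrap
comparison of the full kinematic curves. A synthetic cohort generator with
exact ground truth backs every stage with known-answer tests.

## What it computes

**Events.** Heel strike is a prominent local minimum of the vertical heel
marker; toe-off is the peak of upward toe-marker velocity at push-off. Both
are refined to sub-frame precision by parabolic interpolation (one frame at
60 Hz is 16.7 ms — material for double support). A gait cycle runs from one
heel strike to the next ipsilateral heel strike, and every cycle's curves are
time-normalized to 0–100 % of the cycle (101 points) by linear interpolation.

**Spatiotemporal parameters**, per cycle and averaged per participant after a
pooled ±3 SD outlier screen:

| parameter | definition |
|---|---|
| gait speed (m/s) | forward pelvis displacement over the cycle ÷ duration |
| stride length (m) | forward heel-to-heel distance between ipsilateral strikes |
| step width (cm) | lateral heel separation at the bounding strikes |
| cadence (steps/min) | 120 / cycle duration |
| double support (%) | fraction of the cycle with both feet in stance |
| step-length asymmetry (%) | 100·\|L̄ − R̄\| / (½(L̄ + R̄)) over mean step lengths |

**Peak kinematics.** Fifteen signed peaks per side (pelvis tilt/list/rotation;
hip flexion/extension, adduction/abduction, internal/external rotation; knee
flexion/extension; ankle dorsiflexion/plantarflexion; subtalar
inversion/eversion), taken as maxima/minima of the normalized curves.

**Statistics.** Welch's unequal-variance t-test with Satterthwaite df for
continuous parameters, Pearson chi-square (no continuity correction) for
categorical tables, Cohen's d (pooled SD), with Shapiro–Wilk and Levene
screens reported alongside.

**Phase analysis.** Percentile-bootstrap confidence bands for group mean
curves and significant-region detection for group differences, resampling
participants (m = n−1 per replicate, which makes the bootstrap variance of a
mean exact). A grid point is significant when the CI of the difference
excludes zero; runs shorter than 3 points are discarded.

## Worked example

Simulate one KOA-like participant (parameters drawn from the published
group distributions) and run the full single-trial pipeline:

```python
from kneegait import synthetic as syn, pipeline as pl

cohort = syn.generate_cohort(syn.koa_cohort_spec(n=1, seed=7, trials_per_participant=1))
d = cohort.participants[0]
markers, angles, truth = cohort.trials[d.pid][0]
res = pl.run_trial(markers, angles, pl.RunConfig())
print(res.cycles[["foot", "duration_s", "gait_speed_m_s", "stride_length_m",
                  "step_width_cm", "cadence_steps_min", "double_support_pct",
                  "knee_flexion"]].round(2).to_string(index=False))
```

```
foot  duration_s  gait_speed_m_s  stride_length_m  step_width_cm  cadence_steps_min  double_support_pct  knee_flexion
   L        1.24            0.87             1.08          13.20              96.67               38.92         36.98
   L        1.21            0.88             1.06          13.18              98.97               37.01         37.45
   L        1.20            0.89             1.06          13.20             100.36               38.45         35.80
   L        1.21            0.88             1.06          13.32              99.56               37.74         37.04
   R        1.22            0.87             1.06          13.26              98.09               39.22         35.52
   R        1.23            0.87             1.07          13.20              97.38               37.48         37.04
   R        1.19            0.88             1.05          13.24             100.58               37.69         36.70
   R        1.22            0.88             1.08          13.31              98.51               38.57         35.82
```

This participant's ground truth was speed 0.87 m/s, cadence 98.3 steps/min,
step width 13.23 cm, double support 38.54 %, and a drawn affected-side
(left) peak knee flexion of 37.39° — each per-cycle row above recovers those
values to within the per-cycle jitter the generator injects.

## Command line

```bash
kneegait simulate --group koa --n 10 --seed 1 --out data/koa
kneegait simulate --group control --n 10 --seed 2 --out data/ctrl
kneegait events --trc data/koa/KOA001_T01.trc --out events.csv
kneegait params --trc data/koa/KOA001_T01.trc --mot data/koa/KOA001_T01.mot --out params.csv
kneegait run-all --group-a data/ctrl --group-b data/koa --out report/
```

`run-all` writes the two comparison tables (spatiotemporal and peak angles,
the latter with affected-vs-control and unaffected-vs-control p-value
columns), significant-region CSVs, and band plots.

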