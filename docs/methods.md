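# Methods

## Scope and data model

`kneegait` implements the downstream half of a markerless gait study: it
consumes OpenSim-style TRC marker files and MOT joint-angle files (the
products of video capture, pose estimation, triangulation and inverse
kinematics, which are out of scope) and produces gait events, per-cycle and
per-participant parameters, group statistics, and phase-wise curve
comparisons. The lab frame follows the OpenSim convention: Y vertical,
walking in the X–Z plane (`vertical_axis` is configurable). Marker positions
are stored in their declared unit and converted to metres at a single point
(`io_formats.to_metres`); all computation downstream is metres/seconds/degrees.

## Signal conditioning

Trajectories and kinematic curves are smoothed with a Savitzky–Golay filter,
polynomial order 3, window 31 frames. The protocol this mirrors specifies a
30-frame window; a classic Savitzky–Golay window must be odd, so the nearest
odd value is used (≈0.52 s at 60 Hz) and the effective window is logged.
Interior marker gaps up to `qc.max_gap_frames` (default 10) are linearly
interpolated; longer gaps are bridged only for numerical continuity and
condemn the cycles they touch to QC rejection (`marker_discontinuity`).
Leading/trailing gaps are never extrapolated.

Event detection runs on a *lightly* smoothed copy of the vertical heel/toe
trajectories (`events.smoothing_window`, default 7 frames). This is a
deliberate split: at brisk cadence the 31-frame window spans most of a swing
phase and blurs the sub-cycle contact features that carry event timing, while
the parameters that motivated the heavy window (curve shape, peak values,
positions at strike) still use it. With the light window, detected event
times on noise-free synthetic gait are exact to within 0.1 frame, and with
2 mm marker noise all events stay within 2 frames (the suite asserts ≥95 %).

## Event definitions

* **Heel strike** — local minimum of heel height with prominence above
  0.2 × the trajectory's 5th–95th percentile range, minima separated by at
  least `events.min_interval` (default 0.5 s, a 240 steps/min cadence
  ceiling). Sub-frame refinement fits a parabola through the three samples
  around the minimum; the refinement shift is capped at ±1 frame.
* **Toe-off** — peak of upward toe-marker velocity (central difference of the
  smoothed trajectory), with the same prominence-fraction and refractory
  rules applied to the velocity signal.

Flat trajectories (<1 mm range) yield no events with a warning. Detection is
invariant to vertical offsets by construction.

## Cycles, QC and parameters

A cycle spans consecutive ipsilateral heel strikes. Each dof is interpolated
onto 101 evenly spaced instants across the cycle (0–100 % inclusive — the
gait-literature convention that makes percent indices integral).
QC rejects a cycle when its duration leaves [0.4, 2.5] s (`abnormal_timing`),
an unfilled marker gap longer than `qc.max_gap_frames` overlaps it
(`marker_discontinuity`), or any joint curve leaves its generous anatomical
band — pelvis ±40°, hip −60..70°, knee −20..100°, ankle ±60°, subtalar ±50°
(`implausible_trajectory`). Rejections are logged with one reason code each;
the interactive visual review used in clinical practice is replaced by this
audit trail.

The walking frame is recomputed per trial: forward is the first principal
direction of the pelvis marker's horizontal displacement, oriented along net
travel (trials with <0.5 m of travel are rejected); lateral is its horizontal
perpendicular. Every spatiotemporal parameter is therefore invariant under
lab rotation/translation (asserted in the suite). Gait speed uses pelvis
progression by default (`speed.source=heels` provides the heel-based
fallback); stride, step length and step width are event-anchored heel
positions projected on the forward/lateral axes. Double support intersects
the two feet's stance intervals within the cycle; a leading toe-off or
trailing heel strike contributes a half-open stance interval (the foot was
demonstrably grounded up to/from that event), clipped to the cycle — without
this, the first contralateral cycle of every recording loses a double-support
segment. Step-length asymmetry is evaluated on a participant's *mean* left
and right step lengths; folding |L−R| per cycle first would rectify
measurement noise into a positive bias.

Participant summaries average accepted cycles after a one-pass ±3 SD screen
computed on the pooled (all participants) per-cycle values.

## Group statistics

Continuous parameters always use Welch's t-test (Satterthwaite df); the
Shapiro–Wilk and Levene (median-centred) screens are computed for reporting
only and never switch the test. Chi-square is Pearson without Yates
correction (a flag enables it). Cohen's d uses the pooled-SD form. The
peak-angle table compares each patient side against the control group's
bilateral mean, i.e. the mean of a control participant's left and right
per-side values, formed before any group statistic.

## Phase-wise bootstrap

The resampling unit is the participant (represented by their cycle-averaged
curve), never the cycle — the ~10 cycles a participant contributes are not
independent. Bands and difference tests use the percentile bootstrap
(B = 1000 default, α = 0.05) with **m = n−1 resamples per replicate**: the
naive n-out-of-n bootstrap understates the variance of a mean by (n−1)/n,
which at n ≈ 15–30 per group pushes the pointwise null flag rate above 7 %;
with m = n−1 the bootstrap variance of the mean is exact and the suite's
null-calibration check (200 null repetitions, n = 15/15, B = 500) lands at
5 % ± 2 %. A grid point is significant when the percentile CI of the group
difference excludes zero; flagged points merge into runs and runs shorter
than `min_run` = 3 grid points are discarded, yielding contiguous
"X %–Y %" regions. BCa and random-field/SPM corrections are out of scope.

## Synthetic cohorts

The generator emulates the *measured outputs* of a markerless session for
two groups whose structure follows the published KOA/control tables: gait
speed 0.87/1.24 m/s, cadence 98.30/112.50 steps/min, step width 13.23/8.87 cm,
double support 38.54/22.68 %, asymmetry 7.67/2.75 %, and the fifteen peak
angles per column (affected, unaffected, control-bilateral). Defaults:
3 trials per participant, 4 cycles per trial, 60 Hz, 2 mm white marker noise
(the low end of reported markerless localization error), 2 % CV cycle-duration
jitter, 3 % per-cycle amplitude jitter on joint curves.

Design choices that matter:

* **Balanced draws.** Participant-level parameters are drawn by stratified
  inverse-CDF sampling of the target normal (one jittered quantile per
  stratum, shuffled): each participant is marginally N(mean, SD), but the
  realized cohort mean and SD pin the configured targets, which is what a
  known-answer generator must provide. Draws are truncated at physical
  bounds (e.g. speed ≥ 0.1 m/s, asymmetry ≥ 0); with balanced draws the
  truncation bias is negligible.
* **Internal consistency by construction.** Cycle duration = 120/cadence;
  stride = speed × duration; left/right step lengths split to produce the
  drawn asymmetry; stance fraction = 0.5 + double-support/200 with the
  contralateral foot offset half a cycle. Specs whose speed, stride and
  cadence targets disagree by more than 10 % are rejected at construction.
  The published KOA column is itself only ~9 % self-consistent, so stride is
  the derived quantity and speed/cadence are the drawn ones.
* **Locally symmetric event features.** Heel contact is a symmetric dip
  (2.5 cm deep, ±10 % of the cycle) in an otherwise plateau–swing-bump heel
  profile; toe-off sits at the centre of a symmetric-velocity S-rise with a
  short hold at peak clearance. Symmetric linear smoothing therefore cannot
  bias detected event timing. Events within 0.15 cycles of the trial start or
  0.45 cycles of its end are omitted from the truth tables: their identifying
  signal support is truncated by the recording window and no displacement
  detector can observe them fully.
* **Measured-space peak calibration.** Published peak angles are values
  measured after the smoothing protocol, and a 31-frame window attenuates a
  sharp knee swing peak by up to ~8° at fast cadence. Joint waveforms
  (truncated Fourier series, K = 6, fitted to hand-authored normative control
  points — synthetic shapes, not measured curves) are therefore affinely
  calibrated so that the *protocol-smoothed* curve at the participant's
  cadence reaches the drawn targets. Per-cycle truth accounts for each
  cycle's jittered duration. If angle smoothing is disabled in the analysis
  config, measured peaks will exceed the configured targets by the
  attenuation.

What the generator does **not** emulate: autocorrelated or occlusion-driven
marker noise (white noise, optionally low-pass via the pipeline smoother, is
an acknowledged approximation), per-side pelvis asymmetries (the pelvis is
one segment, so its emitted peaks follow the affected-side column for
patients), kinetics, turning or treadmill gait, and any video-level failure
mode. Passing recovery tests therefore demonstrate the correctness of the
downstream analysis under these idealized conditions, not the accuracy of
markerless capture itself.

## Known-answer experiment and problem sizes

`recovery_experiment` (driven by `scripts/acceptance.py`) generates the two
cohorts at study scale — 78 control and 33 KOA participants, 3 trials each,
4 cycles per trial — writes them as TRC/MOT files, runs the full pipeline on
every trial, and reports cohort means next to the configured targets with
their 1-SE bands (SD/√n of the configured distribution). These sizes were
chosen to mirror the study design while keeping a complete run under a
minute on one CPU; the test suite uses smaller cohorts (3–10 participants)
for per-module checks. Deviations of the recovered cohort means stay within
about half a standard error across seeds; residual biases (draw truncation,
smoothing of heel positions near strikes) are an order of magnitude below
the 1-SE acceptance band.

## Numerical notes and limitations

* Savitzky–Golay edges use the truncated-window polynomial fit
  (`mode="interp"`); series shorter than the window are rejected with advice
  to shrink it.
* Parabolic event refinement is skipped at array boundaries and its shift is
  clipped to ±1 frame; degenerate (flat) neighbourhoods return the discrete
  extremum.
* `time_normalize` is exact for piecewise-linear inputs and idempotent on
  101-point curves; interpolation error is second order in the sample
  spacing.
* The ±3 SD outlier rule is single-pass by design; an all-equal pool keeps
  everything.
* Bootstrap reproducibility is guaranteed only for a fixed seed, B, and
  group sizes.
* The chi-square requires non-empty margins; 2×2 tables with structural
  zeros are rejected rather than corrected.
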