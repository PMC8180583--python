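# Methods

This note documents the models and numerical choices behind `gaitgaze`: what
each analysis stage computes, what the synthetic-data generator does and does
not emulate, and where genuinely open design decisions were resolved.

## The measurement problem

Head-mounted eye trackers report gaze *eye-in-head*: degrees of visual field
relative to the headset, x positive rightward, y positive downward.  Two
device classes are modelled — a VR headset with an add-on tracker (nominal
120 Hz, usable tracking range 100° × 110°) and a mobile real-world tracker
(60 Hz, 60° × 46°).  Three artefacts dominate such recordings:

1. **Invalid samples.** Blinks and tracking loss are flagged by a zero pupil
   size; gaze on those samples is meaningless and set to NaN.  Invalid
   samples stay in the stream because duration bookkeeping (saccade-rate
   denominators, validity logging) needs them.
2. **Headset drift.** The headset slips slowly relative to the head, adding
   an offset that grows over the session.  It is quantified by re-measuring
   the 3×3 calibration grid at session end (offsets `measured − true`,
   summarised by mean vector and mean magnitude).  All spread- and
   velocity-based measures are invariant to constant offsets; only absolute
   medians are affected.  This invariance is enforced by property tests.
3. **Out-of-range samples.** Points outside the manufacturer range have
   unreliable positions but a reliable *side*.  They are therefore retained
   for medians and IQRs, which only need side information, with a
   reliability flag that trips if any side holds ≥ 50% of the data.

## Analysis stages

**Calibration.** Raw readings are mapped onto the known 3×3 marker grid
(spacing 11.5° horizontal, 10° vertical) by bivariate polynomial least
squares, one polynomial per output channel.  Default order is 2 (full
quadratic, 6 coefficients per channel from 9 points); the order is exposed in
configuration since any order with ≤ 9 coefficients is admissible.  Any warp
inside the model class is reproduced to machine precision.

**Sector segmentation.** The walking route is partitioned into labelled
half-open intervals `[t0, t1)` — 6 corridors, 4 ascending-stair segments,
2 descending-stair segments, plus unclassified connecting areas and optional
exclusion windows (external disturbances).  Half-open intervals make the
partition exact: every sample belongs to at most one segment, and
concatenating all labels recovers each in-route sample exactly once.
Excluded samples are flagged, never deleted.

**Descriptive statistics.** Per world × sector cell: componentwise median
and IQR (linear-interpolation quantiles); the **T-shape ratio** — horizontal
IQR of the upper gaze half divided by that of the lower half, split at the
vertical median with ties excluded (> 1 means wider horizontal scanning
above the median, the T-shaped pattern of navigational gaze); **direction
histograms** of sample-to-sample movements in eight 45° wedges centred on
the cardinal and oblique axes (0° = rightward, 90° = upward movement, so the
stored downward-positive vertical displacement is sign-flipped), normalised
to unit integral per individual before any averaging, with the
cardinal/oblique mass ratio as summary; **velocity histograms** in octave
bins (< 1, 1–2, …, 256–512, > 512 °/s, left-closed) over speeds computed
between neighbouring valid samples only — never interpolated across blinks;
and **heatmaps** on a 101 × 101 grid of 1° bins spanning ±50°, out-of-span
mass accumulated in the outermost bins, smoothed by a Gaussian of one bin
full width at half height (σ = 1/2.3548 bins) with reflective boundaries so
total mass is conserved, normalised per participant by their single maximum
bin so relative density across sectors survives, and regularised by +5% of
the scale for logarithmic display.

**Saccade detection.** The velocity-threshold scheme standard for noisy
gaze data: velocities from a centred moving-window differentiator (window
5; the kernel generalises the 5-sample `(x[n+2]+x[n+1]−x[n−1]−x[n−2])/6Δt`
form, shrinking to a 3-sample central difference near the edges of valid
runs so blink-truncated saccades are not silently discarded); per-axis
noise scale from the robust median estimator `σ² = median(v²) − median(v)²`,
estimated per segment because noise differs by terrain and device; a sample
is saccadic when `(vx/λσx)² + (vy/λσy)² > 1`.  The multiplier λ defaults to
6 and is a per-recording parameter, since in practice it is tuned per
participant and device.  Runs shorter than 6 ms are dropped, runs closer
than 20 ms merged, and events never bridge invalid gaps (conservative
truncation).  A constant signal raises an error: the threshold is undefined
at zero noise scale.  Saccade rate = event count / *valid* segment seconds,
which makes the rate first-order insensitive to data loss; residual edge
effects bias it ≈ 3–5% low under heavily fragmented loss (measured on
ground-truth cohorts), which is documented rather than corrected.

**AOI dwell.** Navigational markers arrive as per-frame quadrilateral
corners plus detector confidence; observations with confidence ≤ 0.9 are
discarded.  Gaze-to-AOI distance is Euclidean distance to the *filled*
quadrilateral (zero inside — distance to the outline would differ only
where the rule yields zero anyway); a sample dwells on the marker when the
distance is ≤ 1°.  The dwell denominator is the full analysed segment time;
mean distance averages over AOI-visible frames only.  Because the VR range
far exceeds the real-world one, VR frames are harmonised first: gaze and
the whole quadrilateral must lie inside the centred 60° × 46° range
(extents are stated by the manufacturer; centring them on straight-ahead is
the only symmetric placement).  Mask-based marker fitting uses the
extreme-corner method (foreground extrema under the four diagonal
projections), exact for axis-aligned rectangles and pixel-accurate for
moderate perspective skews.

**Eye-in-world.** The visual horizon is tracked in the scene video by
hybrid manual/correlation tracking: a manual mark every 9 frames anchors a
patch (default 64 px, search ±16 px) that is matched by normalised
cross-correlation in the ±4 neighbouring frames, with parabolic sub-pixel
peak refinement; keyframes pass through their marks exactly, and a peak on
the search-window edge sets a low-confidence flag.  Vertical gaze minus
horizon position (both positive-down, nearest-frame alignment) gives gaze
relative to the world.  Any offset common to gaze and horizon — headset
placement, drift — cancels exactly, which is the point of the referencing.

**Head pose.** The headset's zero depends on placement, so per participant
the mean corridor orientation is the zero reference; per-sector means and
IQRs of pitch (positive down) and roll (positive right) are reported. Yaw is
excluded: it is dominated by route turns, not posture.

**Inference.** Paired t-tests (two-sided, df = n−1) and the within-subject
2 (world) × 3 (sector) ANOVA.  Each effect is tested against its own
subject-by-effect interaction.  Sphericity is assessed per effect by
Mauchly's test on the covariance of orthonormal-contrast subject scores
(the interaction uses the Kronecker product of the factor contrasts); when
Mauchly's p < 0.05 the reported p-value is Greenhouse–Geisser corrected
(F evaluated at ε-scaled dfs, ε = (tr S)²/(k · tr S²), bounded by 1/(k−1)
and 1), with uncorrected dfs and ε reported alongside.  A two-level factor
has one contrast and is spherical by construction (ε = 1 exactly, no ε
printed).  The implementation is verified against an explicit
projection-matrix decomposition (1e-8) and an independent reference
implementation, and its null rejection rate is calibrated by simulation.
No correction for multiplicity across metric families is applied — each
family answers a separate question — and this is deliberate.

## The synthetic-data generator

The generator exists so every stage can be verified against exact ground
truth; its defaults encode the study conditions the pipeline is meant to
handle.

*Gaze process.* An alternating fixation/saccade renewal process per
world × sector cell.  Saccade onsets follow a gamma renewal process
(shape 2) with an 80 ms post-saccadic refractory floor; the gamma scale is
solved numerically so the truncated mean equals 1/rate, making the injected
rate match its target exactly.  Each saccade either (a) with probability
`cardinal_bias` (default 0.6) jumps along a near-cardinal direction
(±6° angular jitter) with gamma-distributed amplitude (mean 4.5°, shape 5,
floor 2.5° so every jump exceeds the detector threshold mid-flight —
sub-threshold drifts are not what the saccade machinery is meant to count),
reflected at a ±3.5 σ box so cardinal directions stay cardinal; or (b)
re-targets a fresh fixation point from the cell's Gaussian scatter
(σx = 6°, σy = 5°).  The upper/lower spread parameter widens horizontal
excursions and the reflection box above the vertical centre, producing
T-shaped maps.  Trajectories follow a raised-cosine velocity profile with
duration 20 ms + 2.5 ms/deg, so peak velocity grows with amplitude
(main-sequence-like).  Measured gaze = process + isotropic fixational noise
(σ = 0.3°) + linear drift.

*Cell means and rates* default to the per-terrain values the statistics are
checked against: vertical medians from ≈ 4.4° (VR corridor) to ≈ 15.2°
(VR descending stairs), per-cell saccade rates 1.64–2.28 s⁻¹ (VR) and
3.27–3.63 s⁻¹ (RW).  The `upper_lower_spread_ratio` defaults are
calibrated once so the *measured* cohort-mean T-shape ratios land at the
study conditions (corridor ≈ 1.16/1.15 up to descending ≈ 2.77); the
measured ratio is an emergent, world-dependent monotone function of the
parameter, because walk and in-flight samples dilute the asymmetry.

*Data loss.* Invalid time is a Poisson union of short blinks (mean 0.15 s
VR / 0.25 s RW) and, for the mobile tracker, extended dropouts (mean 1.2 s,
60% of the loss budget); rates are set via the M/G/∞ busy-fraction identity
`coverage = 1 − exp(−Σ rate·dur)` so expected validity hits its target
(99.5% VR, 85.5% RW) exactly.  An all-blink model reaching 14.5% loss would
need an unphysiological ~0.5 blinks/s.

*Drift* is linear in time (only the endpoint is observable, so the simplest
monotone model is used), magnitude 6.4° (VR) / 10.8° (RW).  In cohorts each
participant's drift direction is random with fixed magnitude: within an
individual all validation points share one offset, across the cohort there
is no directional bias.  Demo horizon traces carry the same session drift
as gaze — both live in the camera frame — so eye-in-world referencing
cancels it.

*Route.* Six corridors, four ascending and two descending stair segments
with 2 s unclassified turns, sector totals per world matching the recorded
session lengths (e.g. corridors 167.5 s VR / 123 s RW).  Head pitch is
offset per sector (descending ≈ 14.6° down relative to corridors) with
smoothed transitions and low-pass noise.

*Ground truth* records every injected saccade, the noise-free process, and
per-sector median/IQR *over the samples the recording exposes* — dropouts
remove whole fixations, so all-sample truth would differ from anything a
pipeline could estimate, for reasons unrelated to pipeline correctness.

*What the generator does not emulate:* smooth pursuit and VOR kinematics,
vergence, saccadic suppression, scene content, and any coupling between
gait phase and gaze.  Passing recovery tests therefore demonstrates that
the estimators are correct under the modelled statistical structure, not
that the pipeline is robust to every artefact of real recordings.  Two
visible simplifications: sector transitions carry the previous sector's
gaze for a moment (a transient that biases short-segment medians by a few
tenths of a degree), and per-sample velocity distributions are dominated by
white fixational noise rather than oculomotor drift.

## Problem sizes and tolerances

Verification cohorts use n = 8 participants (the analysed cohort size) with
both worlds per participant.  Median/IQR recovery uses a doubled route per
session and compares cohort-mean per-cell values (±0.2° medians, ±5%
relative IQRs).  Rate recovery uses doubled sessions and three seeds per
world at targets 2.0 and 3.5 s⁻¹ (±10% at λ = 6); false positives are
checked on 120 s of pure noise (< 0.05 s⁻¹).  The repeated-measures ANOVA
is checked on 100 random datasets against the projection oracle (1e-8) and
calibrated on 2 000 null replicates ([0.03, 0.07] rejection at α = 0.05).
The power/calibration study runs 200 cohorts at a quarter-length route with
additive cell means (a sector effect, no world × sector interaction) and
drift off, since unequal drift ramps would inject a real interaction.
Horizon tracking is verified on 64-frame stacks (RMS ≤ 0.5 px at 1% noise,
zero keyframe error); AOI distance against a dense boundary-sampling oracle
(1 000 pairs, ±0.01°); dwell recovery against 3.5% / 1.8% targets
(±0.5 pp).
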