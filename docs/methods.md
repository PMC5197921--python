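# Methods

This note documents the models, conventions and numerical choices behind
`actiday`, and what the synthetic cohort does and does not emulate.

## Signal model and units

Accelerations are handled in g (1 g = 9.81 m/s²) internally and reported in
mg (10⁻³ g). The sensor model is `measured = gain ∘ a_true + offset + ε`,
applied per axis with gain before offset; autocalibration inverts it as
`(measured − offset) / gain`. The dynamic content of wrist movement is
summarised by the *intensity* λ of a minute: the standard deviation (mg) of
the gravity-removed acceleration magnitude over that minute. The per-minute
activity feature, the mean absolute band-passed magnitude, estimates the
folded-normal mean λ·√(2/π) ≈ 0.8 λ for Gaussian motion; the pipeline's
interpolation and band-pass shave a further ~3 % off this value, which is
irrelevant for group contrasts and correlations (both are invariant to a
common positive scale).

## Pre-processing

* **Autocalibration.** Still windows are non-overlapping 10 s windows with
  per-axis SD below 13 mg; their mean vectors sample the local gravity
  vector at whatever orientations the wrist visited. The fit iterates:
  project the currently-corrected window means onto the unit sphere, then
  per axis regress the projections on the corrected values (ordinary least
  squares with equal weights — the still means are homoscedastic here) and
  fold intercept/slope into offset/gain; iteration stops at a relative
  parameter change below 1e-9 or 1000 iterations. Identifiability requires
  the still means to reach ±300 mg on every axis; otherwise the model is
  returned unsuccessful with identity parameters, and every day of that
  recording is excluded (`calibration_failure`). Success additionally
  requires the residual sphere error to be under 10 mg and not above the
  pre-fit error.
* **Interpolation.** Each axis is interpolated onto a uniform 50 Hz grid
  with a local 4-point piecewise Lagrange cubic: for a grid point in knot
  interval [tᵢ, tᵢ₊₁) the unique cubic through knots i−1…i+2 is evaluated.
  The scheme passes through every knot, reproduces cubic polynomials
  exactly, is local (O(n), no global solve) and handles irregular
  timestamps; it is not C¹ at knots, which is immaterial after band-pass
  filtering and minute-level averaging. Gaps larger than ~5 sample
  intervals (at least 0.5 s) are never interpolated across: grid points
  inside them are missing.
* **Band-pass.** The magnitude is filtered with an order-4 Butterworth
  band-pass (0.2–15 Hz) applied forward–backward (zero phase), so minute
  alignment is preserved and the stationary 1 g component is rejected as
  DC. The first and last 5 s of every contiguous run are discarded as edge
  transients. The filtered magnitude is signed with zero mean; features
  rectify it.
* **Changeover merging.** Two device files from one participant are merged
  onto the first device's clock when the gap is under 1 h; the gap itself
  stays missing. A changeover gap of ~1 min costs at most one feature
  minute. Gaps of 1 h or more are refused and the sessions processed
  separately.

## Wear time and day inclusion

A 30 min midnight-aligned segment is worn iff the SD of its magnitude
samples exceeds 13 mg (strict). A calendar day is included iff worn
> 720 min, calibration succeeded, and no malfunction was flagged
(malfunction is an input, not inferred from the signal). Partial first/last
days normally fall to the half-day rule and are labelled `partial_day`.
Compliance is worn time divided by total time over included days.

## Features and the average day

Minutes are midnight-aligned (each wear segment covers exactly 30 feature
minutes). A minute needs at least 1500 of its 3000 samples (half a minute
at 50 Hz) to be computed; short or unworn minutes are missing, never
zero-filled. Activity and jerk use absolute values because the signed
minute means of a zero-mean signal and its derivative otherwise telescope
toward zero; rectification preserves the reading that sudden movements mean
high jerk. The jerk derivative is the least-squares slope of a centred
5-sample window, Σk·m[t+k]/(10·Δt). Entropy uses 64 fixed bins of width
15.625 mg spanning [−500, 500) mg (values outside clamp into the edge
bins), in bits, so 0 ≤ H ≤ 6 and minutes/participants share one scale; the
binning is a package convention, and entropy is *not* scale-equivariant
under rescaling of m (activity and jerk are). The average day is the
per-minute-of-day mean of each feature across included days, non-wear
excluded; window means (night 00:00–06:00, daytime 06:00–24:00, morning
06:00–12:00, and the whole-day mean used for group tests) are unweighted
means over the window's non-missing minutes.

## Statistics

Confound removal regresses each participant-level measure on an intercept
plus age, BMI and pre-morbid IQ, pooled across groups (pooling preserves
the group contrast while removing confound slopes), and keeps residual +
grand mean. Group differences use two-tailed pooled-variance t tests with
df = n₁+n₂−2 (classical pooled rather than Welch, switchable by computing
on the residualized columns directly). Partial correlations residualize
both variables on an intercept + age, BMI, IQ and sex, correlate the
residuals, and take p from t = r·√((n−k−2)/(1−r²)); they are computed
within each group, with listwise deletion and n reported per pair. Z
composites standardize each test against the control mean and SD, negate
lower-is-better scores (times, error counts) so higher is always better,
impute missing raw scores with the group mean, and average tests within
conceptual domains plus a grand mean. No multiple-testing correction is
applied; outputs say so.

## Synthetic cohort

The generator emulates a two-arm wearable study: each participant records
`n_days` full days plus short partial first/last days (device delivered in
the evening, collected in the morning), at 30 Hz with multiplicative
interval jitter (sd 1e-4), split into two device files at a mid-week
changeover with a 60 s gap on a minute boundary.

* **Intensity profile.** Daytime (06:30–23:00) intensity is a 30 mg plateau
  plus Gaussian bumps at 09:00 (55 mg, σ = 90 min), 15:00 (35 mg, σ = 120
  min) and 20:00 (25 mg, σ = 90 min). Night minutes are an independent
  quiescent/restless mixture (65 % at 2 mg, 35 % at 45 mg): restless
  minutes keep worn night segments above the 13 mg wear threshold, while
  quiescent minutes supply the still windows autocalibration needs. A
  per-participant scale factor ~ N(1, 0.10) models between-person
  variability (a ~10 % coefficient of variation, appropriate for an
  age-homogeneous cohort). The case group's whole 06:00–12:00 intensity is
  multiplied by (1 − δ), δ = 0.3 by default; with the defaults above this
  yields a standardized daytime-mean difference of d ≈ 1.2, i.e. a clearly
  detectable effect at n ≈ 30/group, and d ≈ 2 at δ = 0.5.
* **Dynamic signal.** Within a minute the dynamic component is band-limited
  unit-variance noise (white noise on a 16 Hz grid, cubic-interpolated to
  the native timestamps and renormalised) scaled so the magnitude SD equals
  λ; minutes with λ ≥ 60 mg devote 30 % of that variance to a 2 Hz
  arm-swing sinusoid, giving non-trivial jerk and entropy. Band-limiting
  matters: white noise at the native rate would lose a large variance
  fraction through the 0.2–15 Hz pipeline filter and bias recovery checks.
* **Orientation.** Gravity direction follows piecewise great-circle drift
  (rate ~ |N(0, 0.5°/s)|) within posture epochs drawn from a Poisson
  process on the *active* clock, with a fresh uniform orientation each
  epoch. Because the epoch clock advances only during worn, non-quiescent
  samples, orientation is frozen during non-wear and quiescent sleep —
  still windows are genuinely still — while posture changes across the
  nights guarantee the ±300 mg orientation spread calibration needs.
* **Non-wear.** At most one bout per day (probability 0.3 by default),
  1–4 epochs long, snapped to the 30 min epoch grid between 08:00 and
  22:00. Grid alignment keeps the epoch-level wear truth well defined.
* **Sensor.** Per-device offset ~ N(0, 20 mg) and gain ~ N(1, 0.01) per
  axis, plus 2 mg white sensor noise.
* **Covariates and outcomes.** Age ~ N(74, 6), BMI ~ N(26, 4), pre-morbid
  IQ ~ N(112, 8), sex ~ Bernoulli(0.5), independent of activity. Outcome
  scores (daily-function, quality-of-life, depression-severity and
  paired-associates-error analogues) are linear in the participant's true
  daytime mean intensity and the confounds with Gaussian noise; the
  intensity coefficient is β = ρ·σ_y/σ_x in closed form, so the
  within-group partial correlation given the confounds equals the
  configured ρ exactly in population (defaults +0.60, +0.65, −0.37, +0.40).
  Scores are unbounded Gaussians — no floor/ceiling effects.

**What the generator does not emulate:** biomechanically realistic limb
kinematics, sleep staging, activity-type structure (walking bouts, gait),
device dropout/battery artefacts, temperature-dependent calibration, or
floor/ceiling-censored clinical scales. Passing recovery tests therefore
demonstrates that the pipeline correctly inverts *this* generative model —
calibration, wear, feature, averaging and statistical layers — not that it
is robust to every artefact of real devices.

## Problem sizes and determinism

All randomness flows from `numpy.random.default_rng` seeded per participant
as `[seed, index, stream]`; identical config + seed reproduces
byte-identical outputs, and all writers use fixed decimal formats. The
replicate detection study (10 seeds × 10/group × 2 days, δ = 0.5) uses
one-hour partial-day stubs; the statistical calibration studies (type-I
error, partial-ρ recovery) run at the truth level (no signal synthesis),
200 replicates at n = 29/group. The numerics-heavy kernels (interpolation,
orientation, per-minute accumulation) are numba-compiled with a pure-numpy
fallback.

## Known limitations

* The wear rule operates on the magnitude SD, which is blind to pure
  orientation change; very still wear (e.g. motionless sleep for a full
  30 min segment) classifies as non-wear. The night mixture makes this
  rare in simulation but it is a real failure mode of magnitude-only rules.
* Entropy depends on the fixed binning; comparing across devices with very
  different dynamic ranges would need the bin range revisited.
* Residualizing the confounds *without* a group term (the two-stage
  residualize-then-test design) removes a small share of the null
  between-group variance, making the group t test mildly conservative:
  the measured type-I error at alpha = 0.05 is ~0.04 at n = 29/group with
  three random confounds. A one-stage ANCOVA would be exact; the two-stage
  design is kept because it matches the residual-plus-grand-mean workflow.
* The pooled t test assumes equal group variances; the morning attenuation
  makes case-group variance slightly smaller, a negligible distortion at
  these effect sizes but worth remembering for small samples.
* Partial-day handling assumes the recording clock is correct; no daylight
  saving or timezone logic is implemented.
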