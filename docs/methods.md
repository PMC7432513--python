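# Methods

## The measurement

The quantity of interest is, for each tracked joint *j* and each minute *m*
of a session, the 3-D path length

L_j(m) = Σ_k ‖p_j(t_{k+1}) − p_j(t_k)‖,

summed over *valid* trajectory segments whose later endpoint falls in
minute *m*. A segment is valid when both endpoints are `tracked` or
`inferred` and its time span does not exceed the interpolation gap bound
(default 0.5 s). Assigning each segment to the minute of its later endpoint
makes the binning a partition: minute sums conserve the total path length
exactly, which the tests verify to 1e-9.

Positions are used as reported by the sensor, with no smoothing before
differencing (an optional centred moving average exists but is off by
default). Path length is therefore sensor-noise inclusive — the same
convention as the measurement this package models, which is why absolute
magnitudes depend on the device and frame rate and only *contrasts* between
groups recorded under the same conditions are meaningful.

Of the 25 joints reported per skeleton, 17 are analysed: hands, hand tips,
thumbs and feet are rejected because seated subjects never present them to
the camera reliably; the wrist and ankle carry the hand/foot signal.

### Missing data

A minute with no valid segment is *missing* (NaN), never zero — zero would
fabricate stillness during occlusion. Missing minutes are excluded from all
downstream statistics and from the per-minute group-mean curves.

## Tracking model

Device body slots are not stable identities. Persistent ids 1–6 are issued
in order of first detection. Each track keeps an **anchor**: an exponential
moving average (half-life 2 s) of its spine-base position — a smoothed seat
location robust to fidgeting. When a detection run starts while one or more
tracks are inactive, it is attached to the inactive track with the nearest
anchor if that distance is within the re-identification radius (default
0.5 m, roughly a chair spacing); ties break toward the lower id for
determinism. Otherwise a new id is issued; a seventh identity is a capacity
error, matching the six-body hardware limit.

Per-joint occlusion runs bounded by valid samples and spanning at most
`max_interp_gap` (default 0.5 s) are filled by per-axis linear interpolation
in time and marked `inferred`; the fill is exact for linear motion. Longer
gaps — and gaps at track ends — stay missing, so a subject leaving the field
of view cannot inject a teleport distance. `inferred` samples participate in
path length like `tracked` ones by default (the upstream SDK itself infers
joints); `include_inferred=False` excludes them.

Both thresholds are package decisions: the modelled application never
published them. They are exposed as `GapPolicy` / config keys
`tracking.reid_radius_m`, `tracking.max_interp_gap_s`.

## Statistics

* **Levene gate.** Levene's test with mean centering decides variance
  homogeneity at α = 0.05; the two-sample comparison then uses the pooled
  Student *t* (integer df n₁+n₂−2) or Welch's *t* with Welch–Satterthwaite
  df. This reproduces the mixture of fractional and integer dfs seen in
  published tables of this kind.
* **Cohen's d** is unsigned (direction is reported in prose, not the
  table). Two poolings are exposed: `df_weighted`
  (s² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2), the default) and `equal`
  (s² = (s₁²+s₂²)/2) for summary data whose per-group sizes are unknown or
  implicitly paired. Bands: d < 0.20 below threshold, 0.20 ≤ d ≤ 0.50
  small, 0.50 < d ≤ 0.80 moderate, d > 0.80 large. The printed band
  definitions leave (0.50, 0.51) unassigned; this package resolves the gap
  to "moderate".
* **ROC AUC** is computed as the normalized Mann–Whitney U from midranks —
  identical to the trapezoid area under the empirical ROC curve but with
  exact tie handling. Bands: 0.5 chance, (0.5, 0.7) lower, [0.7, 0.9]
  moderate, > 0.9 higher accuracy; an AUC below 0.5 is flagged as
  chance-or-inverted.
* **Cohen's κ** is unweighted, on exact-agreement count categories pooled
  over subjects and behaviours. The degenerate all-one-cell table returns
  κ = 1 with a warning.
* **Unit of analysis.** `compare_groups` defaults to pooling per-minute
  values across subjects (`unit="minute"`), which mirrors the large-df
  presentation customary in this literature; `unit="subject"` (session
  means) is the statistically conservative alternative, because minute
  observations within a subject are not independent — a plain t-test on
  pooled minutes is anti-conservative whenever between-subject variance is
  appreciable. No multiple-testing correction is applied across the 17
  joints by default (matching the modelled analysis); Holm-corrected
  p-values are available behind a flag as a clearly labelled extension.

## Simulator

Each subject sits at a fixed seat; every joint follows a stationary AR(1)
(mean-reverting, "tethered") random walk around its seated rest-pose
offset, with reversion rate 0.5 s⁻¹ and frame rate 30 Hz by default
(configurable; the modelled device runs at 30 Hz nominal).

**Calibration.** For an isotropic Gaussian per-axis displacement SD *s*,
the expected step norm is E‖step‖ = s·2√(2/π) (the χ₃ mean — derived in
closed form and verified by Monte Carlo in the tests). The observed per-step
displacement variance of the AR(1) with coefficient φ and innovation SD *q*
is 2q²/(1+φ) per axis, plus 2·noise_sd² of sensor jitter. Solving for *q*
makes the expected per-minute path equal the profile intensity exactly at
stationarity, for any frame rate and reversion rate; the tests check it to
2 % over 50 seeded 30-minute sessions (with burst modulation and occlusion
off, to measure the walk's expectation rather than Monte-Carlo noise in the
mean-one multipliers). If the requested intensity falls below the sensor
noise floor, the joint moves at the noise floor and a warning is issued.

**Default intensities** (m/min: trunk ≈ 2–3, elbows ≈ 7, wrists ≈ 13–15,
ankles ≈ 8) are typical seated classroom magnitudes for a control-like
subject. Hand-region joints inherit the wrist intensity, feet the ankle.

**Heterogeneity.** A per-minute gamma multiplier (mean 1, CV 0.5) shared by
all of one subject's joints models bursty movement and realistic
between-joint correlation; `simulate_two_groups` additionally gives each
subject a lognormal intensity factor (CV 0.05). The burst CV dominates and
yields minute-level coefficients of variation ≈ 0.5, the order seen in real
seated recordings. The subject-level CV is deliberately small: the
programmed effect size is defined on the *pooled minute distribution*, and
strong subject-level random intercepts would both decouple that definition
from the realized d and make pooled-minute inference strongly clustered.
Researchers wanting realistic child-to-child spread (closer to CV 0.3)
should raise `subject_cv` and analyse with `unit="subject"`.

**Programmed effect sizes.** Group 2's intensities are scaled by the ratio
*r* solving r = 1 + d·c·√((1+r²)/2), where *c* is the closed-form total
minute CV — this makes the standardized mean difference of per-minute path
lengths equal the programmed *d* in expectation, accounting for the SD
scaling with the mean. Under this near-normal minute distribution the
binormal identity AUC = Φ(d/√2) holds, which the end-to-end tests verify
within ±0.03 at d = 0.8.

**Occlusions.** Joint-level occlusions are a Poisson process (default
0.5 events/min, exponential mean 0.3 s — short enough that interpolation
repairs most of them) and whole-body dropouts are rarer and longer (0.02
events/min, mean 5 s), removing frames entirely and letting a body be
re-detected, sometimes in a different device slot, which exercises
re-identification.

**Determinism.** All randomness flows from a single seed through spawned
child generators per subject, so identical seeds give bit-identical streams
regardless of how many subjects are present.

### What the simulator does not emulate

Articulated biomechanics (joints move as independent tethered walks, not a
kinematic chain), posture changes, standing up/walking, depth-dependent
sensor noise, systematic skeleton-fitting biases for crossed legs, and
cross-camera fusion of two devices. Passing tests therefore demonstrate the
correctness of the *pipeline arithmetic and statistics* under a controlled
motion model, not the fidelity of any particular sensor.

## Problem sizes used in the tests

The end-to-end recovery test uses 34 subjects per group × 30-minute
sessions at 30 Hz (≈ 1020 minute-observations per group); type-I
calibration uses 2000 replicates of 30 i.i.d. minute samples per group
drawn directly from the walk's minute-path law at 10 Hz (the minute-path
shape is frame-rate-insensitive because sampling noise is ≈ 1 % of the
burst variability); simulator calibration uses 50 seeded 30-minute
sessions. These sizes give Monte-Carlo standard errors comfortably inside
the asserted tolerances.

## Known limitations

* Re-identification uses seat proximity only; two subjects swapping chairs
  would swap identities.
* The Welch/pooled gate inherits Levene's modest power at small n.
* Minute-pooled inference ignores within-subject correlation (see unit of
  analysis above).
* Absolute path-length magnitudes are convention-dependent (frame rate,
  noise, smoothing); only like-for-like contrasts are interpretable.
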