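# Methods

This note records the models behind each stage of `ratgait`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions that matter when comparing results.

## Study design being emulated

The package targets the measurement problem of a unilateral rat knee-OA
study: three groups (naive n=4, sham n=6, operated n=6) followed over
postoperative days 9/16/23, with spatiotemporal gait, three-axis ground
reaction forces (GRF), tactile sensitivity, and hindlimb weight
distribution measured longitudinally, and histology (ordinal OARSI grade
0–6 plus lesion size/surface/depth percentages) and serum cytokines
collected at the endpoint.  The effects of interest are small: stance-time
balance and footstrike-phase shifts of 1–3% of a stride (1–25 ms at a
0.16–0.80 s stance range) and vertical/propulsive force reductions in the
operated limb.

## Spatiotemporal gait

A trial is a table of foot-strike and toe-off events per hindlimb with paw
positions in cm.  Conventions:

- **Duty factor** is stance/stride per cycle, averaged over cycles, in
  percent.  A stance that spans its full stride (toe-off coinciding with
  the next strike) is returned as 100% with a degenerate-data warning.
  Toe-offs sort before strikes at identical times, so such a stance
  belongs to the stride it closes.
- **Symmetry** uses the left hindlimb as reference: per left stride, the
  phase of the first right strike inside it; cycles without a right strike
  are skipped.  `reference_limb="RH"` flips the convention for
  operated-limb reporting.  Both symmetry and balance are invariant to
  time shifts and uniform time rescaling.
- **Step width** projects strike positions onto the axis perpendicular to
  the direction of travel and takes |mean(LH) − mean(RH)|.  The travel
  axis comes from a centroid track when available, else from the line
  through the trial's first and last strike positions.  The projection
  (rather than a raw y-offset) makes the metric rotation invariant; this
  choice is a package convention, as is reporting symmetry per trial
  before per-animal averaging.
- **Trial validity**: 2–5 complete cycles and (max−min)/mean of per-cycle
  velocities strictly below 15%.  Per-gait-cycle velocity (same-limb
  strike displacement over strike interval) is the smallest unit on which
  a velocity-change criterion is meaningful.  Rejections carry
  machine-readable codes (`too_few_cycles`, `too_many_cycles`,
  `velocity_drift`).
- Accepted trials are averaged unweighted within animal and timepoint;
  the animal mean is the unit of all group statistics.
- Event tables with out-of-order strike/off pairs are rejected per limb,
  never silently reordered.

## GRF processing

- **Filter**: 4th-order Butterworth low-pass at 25 Hz applied
  forward-backward (`sosfiltfilt`, reflective padding), i.e. zero phase
  with the squared magnitude response.  Only the cutoff is a study
  setting; order and phase handling are package choices recorded in the
  output metadata.
- **Stance detection**: longest contiguous run of vertical force above
  2.5% body weight, then each edge walked outward (capped at 25% of the
  run length) while the signal stays positive.  The window therefore ends
  where the force returns to zero, not at the detection threshold —
  important because normalized impulses are sensitive to the stance-time
  denominator (a threshold-bounded window of a 0.37-s half-sine stance
  would inflate impulses by ~2.7%).
- **Normalization**: forces divided by body weight, time remapped to
  τ = (t − start)/stance and linearly resampled onto a fixed 101-point
  grid.  All nine descriptors are dimensionless; impulses integrate over
  τ (a flag emits body-weight·seconds instead).
- **Features**: the braking/propulsion split is the first fx zero
  crossing with τ ≥ 0.05 (the loading transient is skipped so contact
  noise cannot split the phases); mediolateral peaks are signed maxima on
  τ < 0.5 and τ > 0.5 — signed rather than absolute, a documented
  convention for curves that dip negative.  Missing phases (fx without a
  sign change) yield NaN features with flags, never zeros.  A vertical
  impulse below 0.05 raises a partial-contact warning; exclusion of
  partial strikes is an upstream operator decision.
- **Filter interaction**: the low-pass smears the touchdown/liftoff
  corners of any finite-support stance outward, so on *noise-free
  analytic* curves stance detection widens by a few samples and shifts
  impulses by ~3–5%.  Oracle-equivalence checks against closed forms
  therefore run the pipeline without the filter (the analytic curves are
  band-limited); the filter remains the default for measured or noisy
  recordings.  On smooth curves with zero edge slope, features with and
  without the filter agree to well under 0.5%.

## Video velocity

Frames are background-subtracted (absolute difference), binarized at 25%
of the automatic Otsu threshold, and the unweighted foreground centroid is
converted to cm.  Mean velocity is the net displacement between first and
last valid frames over elapsed time — robust to centroid jitter; an
optional moving-average smoothing of the centroid track exists but
defaults to off, since raw centroids already recover constant-velocity
truth to within one pixel quantization.  Frames with fewer than 10
foreground pixels are invalid rather than contributing jittery centroids.

The Otsu threshold is computed with a midpoint tie-break: on a cleanly
bimodal difference image the between-class variance is exactly constant
across the empty histogram gap, and resolving the tie to the lowest
maximizing bin would place the threshold at the top of the noise mode,
where a 25% fraction of it admits background noise.  The midpoint
convention keeps the fractional threshold inside the gap; the
implementation is verified against an exhaustive between-class-variance
search.

## Behavioral assays

**Up-down threshold.**  The staircase starts at the middle filament of a
log-spaced kit, steps down after a withdrawal and up after tolerance, and
stops four responses after the first direction change (or at a set bound).
The default kit (0.4–26 g, 9 filaments) is a standard rodent set; the
exact forces and the stopping bound are package assumptions, configurable
per study.  The 50% threshold is `10^(x_f + k·δ)` with `x_f` the log10 of
the final filament and δ the mean log spacing.  `k·δ` is obtained by
maximizing the Bernoulli likelihood of the observed responses under a
cumulative-normal psychometric function on log force with spread fixed at
δ — the construction from which the classical pattern-factor tables were
tabulated — and the equivalent k is reported.  Sessions that never change
direction clamp to the kit bounds rather than extrapolating.  Against
step-function observers the median estimate lands within one filament
spacing of truth, the resolution limit of the design.

**Weight distribution** is 100·right/(left+right) per rearing trial,
averaged per animal; it is scale invariant, so growth in total body weight
does not bias it.

## Statistics

- **Null-constant tests**: one-sample t of per-animal means against 0.5
  (symmetry), 0 (balance), 50% (weight distribution) per group and
  timepoint.  Repeated measures are collapsed to per-animal means first;
  no mixed-effects model is fitted.  Zero-variance samples at the
  constant return (t=0, p=1); away from it they are flagged degenerate.
- **Factorial ANOVA**: group × time with interaction, Type II sums of
  squares — order-independent main effects under the unbalanced designs
  that uncontrolled plate contacts produce.  Time is treated as an
  independent factor across animal-timepoint means (a documented
  simplification).  Tukey HSD post hoc tests share the pooled variance;
  with two groups they reduce to the pooled t test.
- **Velocity covariate**: stride length and step width correlate with
  self-selected speed, so their group/time effects come from a linear
  model with trial velocity as covariate; a constant velocity column is
  dropped with a warning.
- **Ordinal and skewed endpoints**: Kruskal–Wallis (tie-corrected) for
  OARSI grades; cytokines pass a Shapiro–Wilk gate (p < 0.05 on raw
  values triggers a log10 transform) before one-factor ANOVA + Tukey.
  Non-detects are excluded, never imputed, with detectability percentages
  reported; analytes below detection everywhere are untestable.
- **Endpoint correlations**: every (behavior, lesion measure) pair is fit
  as `Y = β₀ + β₁X` with Y the lesion measure; the table reports R²
  (equal to squared Pearson r in this univariate setting), β₁ ± SE, p,
  and n.  P-values are unadjusted by default with an opt-in
  Benjamini–Hochberg column.  Operated-vs-contralateral comparisons use
  paired t tests Bonferroni-corrected across timepoints.

Under the null cohort generator each of these tests rejects at the nominal
5% rate (verified over 1000 seeded replicates within binomial bounds).

## Synthetic generators

- **Footfalls**: left strikes at multiples of the stride time, right
  strikes at the symmetry phase, toe-offs at the duty fraction; paw x
  advances one stride length per stride, y is split by the step width.
  Gaussian timing noise (default 2 ms, matching the magnitude of the
  temporal effects of interest) is applied to event times — not durations
  — and clipped at 49% of the neighboring gaps so event order is always
  preserved.  Strike-phase and duty-factor asymmetry are independent
  knobs, since either (or both) may express a unilateral deficit.
- **GRF curves**: Fz is a half-sine; Fx is two *independently scaled*
  sine lobes (braking then propulsive), so unequal braking and propulsive
  peaks are expressible, as the two are independent measures; Fy is two
  half-sine bumps centered at τ = 0.25 and 0.75.  All nine feature truths
  are closed forms (half-sine impulse 2/π × peak; lobe impulse peak/π).
  These are parametric shapes matching the canonical curve morphology,
  not limb-dynamics simulations.
- **Video**: a bright ellipse translating at constant velocity over a
  uniform background with per-pixel Gaussian noise.  Real video has
  nonuniform lighting, body deformation, and shadows; passing recovery
  tests here validates the pipeline arithmetic, not robustness to those
  artifacts.
- **Cohort**: each operated animal receives a deficit severity
  d ~ N(1, 0.25) (0 for controls) that scales its behavioral shifts and
  drives the lesion endpoint linearly (lesion = b₀ + b₁·d + noise), so
  the correlation stage has known ground truth; the null specification
  sets all shifts and the deficit itself to zero.  Behavioral shifts ramp
  ×0.5 → ×1.5 across the follow-up days in the full pipeline, emulating
  progressive asymmetry.  Default effect sizes (e.g. symmetry +0.02,
  balance +2 pp, vertical peak −0.06 BW on the operated limb) sit at the
  1–3%-of-stride scale the instrumentation is designed to resolve.

## Pipeline and reproducibility

One YAML configuration drives simulate → analyze → stats; per-trial seeds
are derived from the run seed by hashing, every table is written with
fixed float formatting and sorted rows, and the manifest records every
generator parameter and seed.  Reruns under a fixed configuration are
byte-identical.  The default synthetic study (16 animals × 3 days) runs
end-to-end in seconds; tests use 2-animals-per-group studies, 100-trial
recovery ensembles, 500 staircase sessions, and 1000 null-cohort
replicates — sizes chosen so the full suite exercises every claim while
remaining quick to run routinely.

## Known limitations

- Forelimb metrics, joint kinematics, and inverse dynamics are out of
  scope, as are paw detection from video and multi-animal tracking.
- The factorial ANOVA does not model within-animal correlation across
  timepoints; with few animals per group this is a real simplification.
- The psychometric-likelihood threshold estimator agrees with the
  classical tabulated factors by construction but is not a table lookup;
  studies requiring the exact historical table values should supply them.
- Mediolateral peak extraction assumes the two-bump morphology; curves
  dominated by a single bump report one peak per stance half regardless.
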