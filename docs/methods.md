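# Methods

`vbtval` implements a complete concurrent-validity analysis for
barbell-velocity measurement systems, together with a synthetic-data
generator that reproduces the statistical structure such a study assumes.
This note records the models, the numerical choices, and what the simulated
conditions do and do not show about real data.

## The measurement problem

In velocity-based resistance training (VBT), the variable of interest is the
mean concentric velocity (MV) of a barbell repetition: vertical displacement
of the bar divided by the duration of the lifting phase, in m/s. A criterion
system (3D motion capture) provides the reference MV; one or more practical
systems (linear transducers, smartphone apps) are judged against it. Error
has several faces: fixed bias (a constant offset), proportional bias (error
growing with velocity, slope ≠ 1), random error, and detection failures —
*missed* repetitions (performed but not registered) and *ghost* repetitions
(registered but never performed, typically unracking artefacts).

## Criterion kinematics

The criterion chain mirrors standard motion-capture processing:

1. **Filtering.** A fourth-order Butterworth low-pass with a 10 Hz cutoff,
   applied forward and backward (zero phase). The two-pass magnitude response
   is `1/(1 + (f/10)^8)`; a 1 Hz movement component passes essentially
   unchanged while 50 Hz noise is attenuated by ~4e5. Edges use reflective
   ("even") padding of 24 samples; trajectories must include at least 0.5 s
   of quiet standing on both sides, which the simulator guarantees.
2. **Differentiation.** Central differences on the vertical coordinate
   (one-sided at the ends). The truncation error for a component of angular
   frequency ω is bounded by ω³h²/6 with h = 5 ms, i.e. ~1.3e-4 m/s for a
   0.5 Hz component — negligible against every tolerance used here.
3. **Segmentation.** Candidate repetitions are maximal contiguous runs where
   vertical velocity exceeds 0.02 m/s (strictly); a run is kept only if its
   net vertical displacement reaches 0.10 m. "Distance" is vertical
   displacement, not 3D path length: the thresholds refer to lifting height.
   Only upward segments count — the concentric phase defines the repetition.
4. **Boundary refinement.** A raw threshold rule clips the low-velocity
   tails of the concentric phase and overestimates MV by 2–5% for fast
   repetitions. Each run boundary is therefore refined: interpolated
   crossing times of levels a·v_peak (a = 0.10…0.70 in steps of 0.05) on the
   outer flank are fit as t(a) = t₀ + c·arcsin(a) and read off at a = 0.
   The arcsine form is exact for a sinusoidal flank and reduces to linear
   extrapolation at small levels, so it behaves sensibly for any flank with
   non-zero onset slope. Crossings require two consecutive samples at or
   above the level so isolated noise blips cannot trigger them. With this
   refinement the pipeline recovers the true displacement/duration ratio
   within 0.41% (worst case) on a noiseless 3-exercise × 10-load grid, and
   within ~1% per attempt under 1 mm white marker noise.
5. **Resolution.** If more segments survive than repetitions were performed,
   the largest-displacement segments are kept (ties: earlier start). This is
   a deterministic stand-in for a manual cross-check against the
   reconstructed bar path; selections are logged.

The velocity threshold is applied to signed (not absolute) velocity; boundary
samples exactly at the threshold terminate a segment. Both choices are
arbitrary at measure zero and fixed for reproducibility.

## Synthetic data

**Cohort.** Body mass and relative strength (1RM per kg body mass, per lift)
are drawn from truncated normal distributions via rejection sampling, using
published sample characteristics of competitive powerlifters (e.g. body mass
83.4 ± 19.8 kg on [55.8, 147.7]; relative squat 1RM 2.32 ± 0.43 on
[1.68, 3.46]). Absolute 1RM = relative 1RM × body mass. Setting an SD to
zero collapses the distribution to its mean, which the tests exploit.

**Protocol.** Single repetitions at 45–90% of 1RM in 5% steps (ten loads per
lift), loads rounded to the nearest 2.5 kg with ties rounding up.

**Trajectories.** Movement phases are half-cosine position segments, so
velocity is a half-sine pulse: boundary velocities are exactly zero and
displacement, duration and MV have closed forms. Phase order is
exercise-specific — squat: descent then ascent; bench press: descent, pause
(0.8 s default), ascent; deadlift: ascent first, lockout hold, lowering.
Phase durations are quantized to the 200 Hz sample grid so the returned true
MV is exact. The target MV falls linearly with load fraction between two
anchors (defaults: squat 0.90→0.30, bench 0.75→0.17, deadlift
0.80→0.25 m/s from 45% to 90% 1RM), spanning roughly 0.1–1.0 m/s overall, in
line with the velocity range such loading protocols produce. An optional
"sticking region" dip subtracts a Gaussian velocity bump (width T/8) centred
mid-concentric; its coefficient is calibrated by bisection so the dip bottom
sits at (1 − depth) of the realized peak, and the amplitude is rescaled so
displacement is conserved exactly (erf closed form). White Gaussian position
noise (default 0.5 mm, emulating residual marker noise) is added last; the
returned ground-truth MV is always the noiseless value.

In the full-study pipeline each lifter's load-velocity line is additionally
shifted by a subject-specific offset (SD 0.03 m/s, clipped so the heaviest
load stays liftable), giving realistic between-subject velocity spread while
keeping `simulate_trajectory` itself a pure function of (exercise, load
fraction, config, seed).

**Devices.** A practical device observes
`MV_obs = (α + u0ᵢ) + (β + u1ᵢ)·MV_true + ε`, with subject effects
(u0ᵢ, u1ᵢ) drawn once per subject per device from a 2×2 covariance and
ε ~ N(0, σ²). Observed velocities are floored at 0.005 m/s (devices never
report non-positive MV; the floor is far below any realistic observation).
Each repetition is missed independently with probability `miss_prob`
(emitted with status `missed`, no velocity); each set spawns a ghost with
probability `ghost_prob` (small velocity, status `ghost`). Ghosts are
excluded from the paired analysis and counted separately — they are not
missed repetitions.

**What the generator does not emulate.** No video capture, camera
distortion, plate-diameter scaling, tether geometry or barbell tilt — device
error is phenomenological at the MV level. Miss probability is constant per
device, not velocity- or ROM-dependent. Horizontal bar-path curvature (the
bench "J-curve") is not modelled; the criterion uses vertical displacement
only, so this does not affect the quantities under test. Passing tests
therefore demonstrate that the *analysis* machinery is correct and
well-calibrated under the assumed error structure, not that any particular
real device conforms to that structure.

## Pairing and bookkeeping

Criterion and practical repetitions are matched within each
(subject, exercise, load, set) cell in repetition order. With single-rep sets
(the study protocol) this matching is exact; multi-rep sets are supported by
the same rule. Unmatched criterion reps count as missed; practical ok-reps in
excess of the criterion count within a set are labelled ghosts (the unracking
signature). The invariant `paired + missed = criterion reps` is enforced per
device at the end of every run. Missed rate = missed / (paired + missed).

## Validity models

Analysis is per practical device and per exercise; nothing is pooled.

**Model 1 (calibration).** Practical MV as a linear function of criterion
MV with correlated random intercepts and slopes per subject. Both axes are
centred and scaled by the criterion mean and SD before fitting; intercept,
slope and residual SD are back-transformed to natural units for reporting.

**Model 2 (mean difference).** Each paired repetition contributes two rows
(criterion, source = 0; practical, source = 1); velocity is modelled on the
source indicator with a random intercept and a random source effect per
subject. The source coefficient δ is the mean device-criterion difference.

**Priors** (standardized scale): N(0, 1) on coefficients, half-N(0, 1) on
the residual SD and random-effect SDs, LKJ(2) on the random-effect
correlation. These are conventional weakly informative defaults; scales are
configurable.

**Sampler.** The random effects are Gaussian and enter linearly, so they are
marginalized analytically — per subject the marginal covariance is a rank-2
update of σ²I, handled with 2×2 Woodbury identities in a form that remains
valid when a random-effect SD is exactly zero. Ensemble MCMC (emcee with
differential-evolution moves, 32 walkers) explores the six remaining
hyperparameters on their natural scales with hard support bounds; walkers
start from a moment-based estimate. Defaults: 1500 warm-up steps, then 1500
retained steps thinned by 12 → 4000 draws; a "fast" preset (1000 + 1000,
thin 10 → 3200 draws) is used in simulation studies. Subject effects are
then drawn exactly from their conditional Gaussian for each retained draw,
so posterior predictions include subject-level shrinkage without any
approximation. For split-R̂ the walkers are grouped into four long chains
(interacting walkers make many short walker-chains overstate disagreement
even for effectively independent draws); ESS is computed on ungrouped
walkers, which is the conservative direction. A fit is flagged (never
silently dropped) if any reported parameter has R̂ ≥ 1.01.

**Derived statistics**, per posterior draw:

- **RMSE** = √(mean over reps of (ŷ − y)²), with ŷ the draw's conditional
  expectation (fixed + subject effects, *no* residual draw added). Adding
  residual noise would inflate RMSE toward √2·σ; the conditional-mean
  definition makes RMSE ≈ σ for a correctly specified model.
- **R²** = Var(ŷ) / (Var(ŷ) + Var(y − ŷ)) over the dataset (the standard
  Bayesian R²).
- **SMB** = δ / SD of the criterion MVs of the analyzed exercise × device
  dataset. The criterion-anchored standardizer keeps SMB unit-free and
  comparable across exercises; a pooled-SD alternative would change only the
  scale, and SMB·scale equals δ draw-by-draw at machine precision.

All are summarized by the posterior mean and 95% highest-density interval
(shortest contiguous interval containing ⌈0.95·n⌉ sorted draws).

## Equivalence testing (ROPE)

The practical meaning of a device's error is judged against a *reference
device* rather than an absolute cut-off. For each statistic the reference
posterior's 95% HDI limit farther from the perfect value (intercept 0,
slope 1, R² 1, RMSE 0, SMB 0) defines the region of practical equivalence:
symmetric about the perfect value for intercept, slope and SMB; one-sided
[lower limit, 1] for R² and [0, upper limit] for RMSE, because those
statistics are boundary-perfect. ROPE bounds are inclusive; directional
probabilities use strict inequalities.

A device is labelled `likely_equivalent` when at least 95% of its posterior
mass falls inside the region, `likely_different` when at most 5% does — or
when at least 95% of mass lies beyond one region edge while membership misses
its threshold — and `unclear` otherwise. A membership probability of 94.5%
therefore yields `unclear`, not a "likely" claim. By construction the
reference's own posterior always satisfies the membership rule against its
own region.

One consequence worth knowing: a second device that is *statistically
identical* to the reference typically lands at membership ~0.85–0.95, i.e.
`unclear`, because its posterior has the same width as the region. Clear
equivalence requires the device to be at least as precise as the reference;
clear difference requires a genuine effect. The end-to-end tests encode this:
an exact-identity device earns `likely_equivalent` across the board, a
same-grade device earns mostly-equivalent with boundary `unclear` cells, and
a degraded device is flagged on RMSE and R².

## Problem sizes and defaults in the shipped analyses

The full simulated study uses 20 subjects × 3 exercises × 10 loads
(600 attempts), a faithful reference (σ = 0.02 m/s, small subject effects)
and a degraded app (α = 0.05, β = 0.85, σ = 0.08, 8% missed, 2% ghosts).
Recovery simulations use 20 seeded replicates of 600-rep datasets at the
fast sampler preset; the discrimination study uses 16 subjects and three
seeds. The acceptance script reruns the study at the default preset and
reports criterion descriptives, missed rates, the reference's posterior
summaries, ROPE membership, sampler diagnostics and bias recovery.

## Known limitations

- Device error is homoscedastic within an exercise; real optical systems may
  show velocity-dependent noise. A heteroscedastic residual model is a
  natural extension.
- Ghost repetitions are generated at the set level with a fixed probability;
  real ghosts cluster around unracking and re-racking events.
- The ensemble sampler's walkers interact, so the grouped-chain R̂ is a
  stationarity diagnostic rather than a between-independent-chain one;
  the calibration test (HDI coverage across replicates) provides the
  stronger end-to-end check.
- The ROPE construction inherits the reference's posterior width: with very
  few subjects the regions widen and every comparison drifts toward
  `unclear`. Analyses require at least 2 subjects and 10 paired reps per
  cell; below study-like sizes (~6 subjects) the SMB comparison in
  particular loses resolution.
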