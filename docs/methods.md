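# Methods

This note documents the statistical model behind `efieldstats`, the
choices made where the design was genuinely open, and what the synthetic
cohort does and does not emulate.

## Outcome measure and ROI averaging

The outcome throughout is the region-of-interest mean E-field magnitude
in V/m: the Euclidean norm of the field, averaged over a 10 mm-radius
sphere at the cortical projection of the stimulation site (C3 → motor
(−52.2, −16.4, 57.8); F3 → prefrontal (−35.5, 49.4, 32.4), MNI mm),
restricted to gray matter. `field_roi` abstracts a solver mesh as
weighted point samples (element centroid + volume); this keeps the
operator independent of any solver's native format and makes it testable
against brute-force enumeration. Whether the original mesh average was
volume-weighted is not recoverable, so weighting is configurable and
defaults to volume-weighted (the natural reading of a mean over a
tetrahedral discretization). Mean-of-magnitudes is used rather than
magnitude-of-mean: the conventional ROI measure averages the magnitude
field. The sphere boundary is closed (≤ radius).

## ANOVA from sufficient statistics

A one-way fixed-effects ANOVA requires only per-group (nᵢ, x̄ᵢ, sᵢ):

- SS_between = Σ nᵢ (x̄ᵢ − x̄)², df_between = k − 1
- SS_within = Σ (nᵢ − 1) sᵢ², df_within = Σ (nᵢ − 1)
- F = (SS_b/df_b)/(SS_w/df_w), η²ₚ = SS_b/(SS_b + SS_w)

Template heads enter the omnibus comparison as singleton (n = 1) groups
contributing zero to SS_within and zero to df_within. For N = 195
individuals plus two templates this gives df = (2, 194) — the only
accounting consistent with 197 observations in 3 groups. The raw-data
route (`anova_from_raw`) is implemented as an independent sums-of-squares
decomposition and cross-checked against the summary route to 12
significant digits, and against `scipy.stats.f_oneway`.

Tukey–Kramer post hocs use q = |x̄ₐ − x̄ᵦ| / √((MS_w/2)(1/nₐ + 1/nᵦ)) with
p from `scipy.stats.studentized_range` at the pooled df. Post hocs are
meaningful only on multi-subject factors, so singleton groups are
rejected with an instruction to exclude templates. With k = 2 the
procedure reduces exactly to the pooled two-sample t-test (tested). The
Monte-Carlo oracle for the adjusted p simulates the studentized-range
null directly (range of k standard normals over √(χ²_df/df), 10⁶ draws).

Percent differences are denominated by the multi-subject group mean:
(x̄ − template)/x̄ × 100, positive when the template underestimates.
No multiple-testing correction is applied across the twelve ANOVAs the
pipeline runs; the report notes this.

p-values are stored at full precision; the text report prints F to 2
decimals, η²ₚ to 3, TMS fields to 2 and tES fields to 3 decimals. α =
0.05 two-tailed throughout.

## Corridor of stability and point of stability

For subsample sizes s = min_size…max_size (default 1…N), the module asks
when subsample means become and remain "stable". Two dimensions of the
procedure are ambiguous in the literature this mirrors, so both are
explicit configuration rather than silent choices:

**Corridor construction.** `sample_percentile` (default) takes the (5th,
95th) percentiles of the raw observations, with the percentile definition
fixed to linear interpolation between closest ranks and recorded in the
result metadata (P5/P95 of 195 values is definition-sensitive). This is
the literal "90% of the sample" corridor — but note it is wide relative
to the sampling error of a mean: subsample-mean bands typically sit
inside it from very small sizes, so it yields small POS values.
`mean_relative_width` builds mean·(1 ∓ w) (default w = 0.05); on data
with a coefficient of variation near 0.2 this is the reading that
produces POS estimates in the several-tens range. `mean_ci` builds the
normal-theory CI of the full-sample mean.

**Stability criterion.** `band_within_corridor` (default) draws
`reps_per_size` (default 10,000) independent subsamples at each size and
requires the (5th, 95th) percentile band of their means to lie inside the
corridor at s and at every larger size up to max_size — not merely the
next size. `trajectory_quantile` instead draws 10,000 growing subsamples
(one permutation each), computes each trajectory's own entry point (the
size from which its running mean stays inside the corridor), and reports
a quantile (default 95th) of those entry points. The two readings
correspond to "independent subsamples per size" versus "accumulation
trajectories"; both are legitimate interpretations of a
subsample-until-stable procedure and they do not coincide.

Sampling is without replacement by default — subsamples of a fixed cohort
of real scans cannot repeat a subject — so the band at s = N has zero
width and the POS always exists when the full-sample mean is inside the
corridor. With-replacement sampling is available for bootstrap-style use.

Numerical details: per-size random streams are derived from the master
seed as `SeedSequence(seed, spawn_key=(size,))`, so results are invariant
to evaluation order; corridor containment is tested with a relative
tolerance of 1e-12 so that constant data (zero-width corridor) yields
POS = min_size despite floating-point summation; a degenerate corridor on
non-constant data raises.

A closed-form Gaussian check: under the relative-width corridor and band
criterion, the subsample mean at size s has SD ≈ σ·√((N−s)/(N·s))
(finite-population correction), so POS ≈ the smallest s with
z₀.₉₅·σ·√((N−s)/(N·s)) ≤ w·μ. Simulation at 2,000 reps agrees with this
approximation within ±6 on Gaussian cohorts (tested), and the
Monte-Carlo jitter of the POS under doubling of reps toward the default
10,000 is within ±3 across seed replicates (tested at sizes capped at
100 to bound runtime; measured jitter is ≤ 1).

Published POS values for analyses of this design depend on the exact
corridor construction, which is under-specified and distribution-shape
dependent; the package therefore validates the machinery by these
properties rather than by matching printed POS numbers. On the default
synthetic cohort with the w = 0.05 relative corridor, all four protocols
stabilize in the 30–50 range — comfortably below the 152 scans that make
up the MNI-152 composite, which is the qualitative claim of interest.

## Synthetic cohort generator

The generator emulates the *statistical* structure of a 195-subject
transdiagnostic TMS cohort; it makes no claim of anatomically realistic
spatial field structure (no MRI, meshing, or FEM is involved, and none is
in scope).

Default study conditions (the packaged `default_cohort.yaml`): five
diagnostic groups of 31/87/31/25/21 (healthy, alcohol use, tobacco use,
generalized anxiety, depression); 106 men / 89 women assigned by global
proportion independent of diagnosis (the sex-by-diagnosis cross-table is
not published); rMT ~ Normal(50.46, 8.91²)% truncated to [31, 78]%,
treatment intensity 120% rMT capped at 100% of stimulator output, maximal
coil dI/dt 150e6 A/s; tES fixed at 2 mA; per-(diagnosis, protocol)
E-field means/SDs as tabulated in the config. The pooled moments implied
by the five-group mixture reproduce the configured transdiagnostic row
(85.26/15.54 V/m for motor TMS) to printed precision.

Distributional choices, since only means and SDs are published: E-fields
are normal, truncated at zero by residual resampling (cells sit ≥ 4.5 SD
above zero, so the truncation perturbs moments by ~2e-6 SD); rMT is a
truncated normal via inverse-CDF. A subject's four protocol values share
one standard-normal latent factor with loading λ = 0.5 on each
standardized deviation (cross-protocol correlation λ² = 0.25) — the same
head drives all four models, so independence would be unrealistic; the
marginal cell moments are unaffected.

Two generation modes: `direct` (default) draws E-fields from the cell
distributions directly. `mechanistic` composes E = gain × dose, with dose
= dI/dt at 120% rMT for TMS and the fixed 2 mA current for tES, and a
lognormal per-subject anatomical gain (positivity) moment-matched per
cell so the marginal moments are recovered; gain and dose are
independent, so matching requires the target cv to exceed the
dose-induced cv (≈ 0.167 under the default rMT distribution, computed by
quadrature on the truncated-normal dose). Four of the ten default TMS
cells fall below that bound, so mechanistic mode refuses them with a
calibration error naming the cell — the default moments are simply not
consistent with a dose-independent gain of arbitrary low variance, which
is itself informative. Mechanistic-mode tests use feasible
parameterizations.

Reproducibility: all randomness derives from one master seed; named
sub-streams (rMT, sex permutation, latent factor, per-protocol residuals)
are indexed per subject, so cohort content is independent of generation
order and identical across runs.

Template heads are plain per-protocol constants with no covariates (their
demographics are not published). The two motor-TMS template values
(78.16, 81.46 V/m) are attributed to the two templates inconsistently
across the source tabulations; the default follows the assignment under
which MNI-152 runs 8.3% below the cohort mean (consistent with the
verifiable percent differences). The omnibus F is invariant to the swap
(tested); percent differences are not, and the analysis report carries a
note to that effect.

What passing tests on synthetic cohorts do **not** show: anything about
real inter-subject anatomical covariance (scalp-to-cortex distance, skull
composition), about non-normal tails of real E-field distributions, or
about spatial field structure. They do show that the statistical
machinery — ANOVA accounting, post-hoc calibration, corridor/POS logic,
moment recovery — is correct under the stated distributional assumptions.

## Problem sizes used in the tests

Moment-recovery checks run at n = 50,000–100,000 per cell (tolerance
3·SD/√n for means); stability property tests run at 2,000 reps per size
with 10–20 seed replicates and sign tests; the acceptance recomputation
runs the four stability analyses at the full default 10,000 reps per
size. The complete default stability run (4 protocols × 195 sizes ×
10,000 reps) takes well under a minute on one CPU.

## Known limitations

- No per-diagnosis POS estimation (the smallest default group has n = 21,
  too few for a stable within-diagnosis corridor); no mixed-effects,
  repeated-measures, covariate-adjusted, or age models.
- No percentile-based (e.g. E100) or normal-component outcome measures;
  the ROI operator consumes point samples, not solver meshes.
- The omnibus design treats template values as fixed singleton
  observations; uncertainty in the template model itself is not modeled.
- Group-summary inputs are printed (rounded) values; statistics computed
  from them inherit that rounding (e.g. an F of 5.949 where full-precision
  inputs may have printed 5.96).
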