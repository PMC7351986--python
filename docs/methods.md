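# Methods

## Scientific setting

Whiplash-associated disorder (WAD) after a motor-vehicle collision leaves a
subset of patients with persistent disability. A candidate imaging phenotype
is muscle fat infiltration (MFI) in the deep cervical extensors (multifidus
and semispinalis cervicis, analysed as one compartment per side): MFI
concentrates medially, next to the spinous process, and its magnitude in the
most-medial portion distinguishes poor recovery from good recovery at one
year. This package implements the full quantitative chain needed to study
that geography: voxelwise fat-fraction mapping, medial→lateral quartile
partitioning of muscle ROIs, per-vertebral-level aggregation, Neck Disability
Index (NDI) recovery-group classification, participant-flow accounting, and
per-level repeated-measures linear mixed models — together with a synthetic
Dixon-cohort generator so every stage is testable end to end without any
imaging download.

## MFI mapping

From fat/water-separated images (2-point Dixon), each voxel's MFI is the pure
signal ratio

    MFI = 100 · I_F / (I_F + I_W)

with I_F the fat and I_W the water intensity. The ratio is invariant to any
common intensity scaling, so no normalisation or bias-field correction is
applied. Voxels with I_F + I_W = 0 carry no measurement: they are flagged
invalid (NaN) rather than assigned 0 or 100, and they are excluded from every
downstream mean. A region whose voxels are all invalid raises a distinct
"no measurable tissue" error rather than reporting 0 %.

## Quartile geometry

Each per-slice, per-side ROI is partitioned into four contiguous
medial→lateral quartiles, Q1 abutting the spinous process and Q4 most
lateral. The medial-lateral coordinate of a voxel is its unsigned
image-column distance from a per-slice spinous-process landmark column; the
axis is therefore anatomical and auditable, not a data-driven principal axis.
Two partition rules are provided:

* **equal-area** (default): voxels sorted by (coordinate, row, column) are cut
  into four rank bins whose sizes differ pairwise by at most one, with larger
  remainder bins placed medially first. Equal voxel counts make the four
  per-quartile means equally precise. Ties in coordinate are broken by
  row-major order, so the partition is deterministic.
* **equal-width**: four equal bands of the coordinate range (`--quartile-rule
  width`), retained because the historical segmentation protocol's exact rule
  is not recoverable; both conventions stay available in configuration.

Slices are partitioned independently; a slice-side with an empty ROI is
recorded as missing, never fatal.

## Aggregation

The unit of analysis is one row per participant × level (C4–C7) × quartile.
For each level the three slices centred on the level's annotated slice range
are used (the central slices are least affected by level-boundary
ambiguity). Left and right voxels of a quartile are pooled across those
slices before averaging, which weights by measured tissue; averaging the two
side means first is available via `bilateral: side-mean`. Cells with zero
valid voxels propagate as missing rows — mixed models tolerate unbalanced
data and nothing is imputed.

## Recovery groups and participant flow

Groups are a pure function of the 12-month NDI %: severe ≥ 30, mild [10, 30),
recovered < 10. The mild band is read as half-open so the three bands tile
[0, 100] even at non-integer NDI values. Flow accounting enforces the
arithmetic identities `returned = enrolled − attrition` and `included =
returned − poor-quality − not-amenable` by construction; quality flags may
only exist for returnees, and amenability is judged only on scans of
acceptable quality.

## Mixed model

Each cervical level is analysed with its own repeated-measures linear mixed
model (REML, statsmodels `MixedLM`):

* **Fixed effects**: group (3 levels, reference *recovered*), quartile
  (4 levels categorical, reference *Q4*; the medial-lateral profile is
  non-linear, so quartile is not treated as numeric in the mean structure),
  their interaction, and age, sex and BMI as covariates.
* **Random effects**: per-participant intercept plus a random slope on the
  numeric quartile index 1–4, with an unstructured 2×2 covariance. The slope
  captures inter-participant differences in the medial→lateral change of MFI;
  a full categorical random quartile effect would be over-parameterised at
  n ≈ 61.
* **Covariates** are centred at the sample mean, so the intercept and all
  marginal group contrasts are evaluated at covariate means. A covariate that
  is constant within a level's table is not estimable and is dropped from the
  design.

Pairwise intra-quartile group contrasts (severe−recovered, mild−recovered,
severe−mild within each quartile) are Wald t-tests on linear combinations of
the fixed effects, i.e. estimated-marginal-mean differences at covariate
means. Degrees of freedom follow a containment-style rule: group contrasts
are between-participant comparisons and use `n_participants − rank(between-
participant design)` (61 participants, six between columns → df = 55); the
group×quartile interaction omnibus, a within-participant comparison, uses the
residual df. The df method is recorded in every result object. Contrast
p-values are unadjusted by default, matching common pairwise-comparison
practice at α = 0.05; Bonferroni is available by flag (family = all contrasts
of one level's model).

### Degenerate inputs

A table with zero residual variance (a fully noise-free synthetic cohort)
makes the mixed likelihood singular. `fit_level_model` detects a
least-squares residual mean square below 1e−10 and returns the exact OLS
solution flagged `degenerate`, with all variance components reported as 0;
contrast standard errors are then 0 and p-values degenerate to 0/1. A
non-converged REML fit is flagged and its contrasts are suppressed.

### Degenerate-limit equivalence

For a balanced, complete two-factor design the GLS estimator of the fixed
effects coincides with OLS for *any* random-intercept/slope covariance,
because the random-effects projection keeps the saturated group×quartile
design space invariant. Participant-level covariates break this invariance
when a random slope is present (the design lacks covariate×quartile columns),
so the package's exact-equivalence check uses a cohort with shared covariate
values — there the identity is algebraic and the observed agreement
(~1e−13) tests the estimation machinery itself rather than Monte-Carlo
noise. With varying covariates the equivalence is asymptotic only.

## Synthetic cohort generator

The generator emulates the analysed study conditions: group sizes 10/26/25
(severe/mild/recovered), NDI drawn uniformly within each group's band (the
least-assumptive band-respecting choice), demographics sampled from the
published group descriptives (e.g. severe: age 37.0 ± 12.5 y, BMI
25.7 ± 2.8 kg/m², 80 % female), ages truncated to the inclusion band 18–65 y.

Imaging is an axial stack of `4 levels × slices_per_level` slices
(default 3 per level, matching the three-slice-per-level measurement rule)
with bilateral elliptical ROIs (default semi-axes 20 × 8 voxels on a 64 × 128
grid) mirrored about a fixed spinous-process landmark column. The voxelwise
target fat fraction in quartile q of level ℓ is

    m = clip(μ[group, ℓ, q] + b0 + b1·q, 0, 100),

with per-participant random effects b0 ~ N(0, participant_sd²) and
b1 ~ N(0, slope_sd²) shared across levels. Intensities invert the MFI ratio:
`water = W·(1 − m/100) + ε`, `fat = W·m/100 + ε`, with W = 1000 intensity
units, ε ~ N(0, voxel_noise_sd²) and intensities truncated at zero. Gaussian
(not Rician) noise is a deliberate desk-scale simplification, exposed in
configuration. All randomness derives from one master seed hashed with the
participant id, so generation is order-independent and bit-reproducible.

### Calibration of the default profiles

The source study reports its quartile profile only graphically, so the true
per-quartile means are unknown and remain configuration, not fact. Defaults
(MFI %, Q1..Q4): recovered (20, 14, 12, 12) at every level; mild Q1 = 26 and
severe Q1 = 28 at every level; Q2 raised to 17 (mild) / 18 (severe) at C4–C5
only; Q3/Q4 never differ between groups. Default variation: participant_sd
3 %, slope_sd 0.8 %/quartile, voxel_noise_sd 30 intensity units. These values
encode the reported qualitative geography — Q1 highest everywhere, symptomatic
elevation in Q1 at all levels and Q2 at C4–C5 only, no lateral group
differences — at the study's group sizes, and the operating-characteristics
study (below) verifies that the significance pattern emerges from them.

### Known ratio bias of the noise model

With additive noise on both channels, E[F/(F+W)] differs from m/100 by
≈ (2m/100 − 1)·σ²/W² (about −0.15 MFI % at σ = 50, W = 1000, m = 20 %). This
is a property of the stated noise model, not an implementation artefact; the
Monte-Carlo test therefore validates pipeline means against an independent
scalar simulation of the same model rather than against the noiseless target.

### What the generator does not emulate

Realistic cervical anatomy, pulse-sequence physics, Rician magnitude noise,
motion/aliasing artefacts, partial-volume effects at muscle boundaries,
segmentation error, and time points other than 12 months. Passing tests
therefore demonstrate the correctness and statistical calibration of the
analysis chain under the stated generative model — not the clinical accuracy
of MFI measurement on real scanners.

## Operating-characteristics studies

`power_typeI_study` simulates replicate cohorts at the *analysis-table* level:
cell mean + random effects + a record-level residual (`measurement_sd`,
default 1.0 MFI %) standing for pooled voxel noise plus the slice/segmentation
variability a real measurement carries. The voxel stage is a linear average,
so this is the distributional image of the full pipeline at a fraction of the
cost; the zero-noise round-trip and Monte-Carlo tests separately pin the
voxel stage itself.

Problem sizes: the null (type-I) study uses 200 replicates of scaled-down
10/10/10 cohorts at one level; the power/geography study uses 100 replicates
at the study's 10/26/25 sizes across all four levels. These sizes give
Monte-Carlo standard errors of ~0.015 on a rate of 0.05 and ~0.04 on a rate
of 0.8, adequate for the qualitative claims being checked.

## Numerical choices

* REML optimisation: L-BFGS with Powell fallback, 200 iterations max;
  convergence status is part of every result.
* Degenerate-table threshold: OLS residual MS < 1e−10.
* Quartile tie-break: row-major; remainder bins medial-first.
* Slice selection: midpoint slice ± 1 of each level's range
  (`floor((lo+hi)/2)`), deterministic.
* Clipping: target fractions to [0, 100], intensities to ≥ 0.
* Seeds: all derived sub-seeds are SHA-256 hashes of (master seed, key)
  truncated to 32 bits.

## Limitations

* The containment-style df is an approximation; Satterthwaite/Kenward-Roger
  are not implemented. The null simulation shows the realised type-I rate of
  the Q1 between-group contrast is close to nominal at n = 30.
* Lateral-quartile contrasts are mildly conservative in simulation (rejection
  somewhat below α), a consequence of the shared random-slope variance
  entering their standard errors.
* True per-quartile effect sizes are unknown (see calibration); all
  magnitude-dependent conclusions are conditional on the configured profiles.
* The equal-area/equal-width choice and pooled/side-mean choice are genuinely
  open conventions; both are configuration switches and defaults are stated
  above.
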