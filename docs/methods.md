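# Methods

This note documents the models implemented in `glycanclock`, the
assumptions behind them, the defaults of the synthetic-data generator,
and the numerical choices that a maintainer would otherwise have to
reverse-engineer from the code.

## The classical twin model

A twin pair's phenotypes (y₁, y₂) are modelled as bivariate normal with
per-individual mean x′β and covariance

    Σ_z = [[v, ρ_z], [ρ_z, v]],   v = a² + c² + e²,
    ρ_MZ = a² + c²,   ρ_DZ = ½·a² + c².

The three variance components have the usual behavioural-genetics
reading: **A** (a²) is additive genetic variance, shared completely by
monozygotic co-twins and half-shared by dizygotic co-twins (the ½ is the
standard assumption of the classical twin design: DZ twins share on
average half of their segregating alleles, with no dominance,
assortative mating, or gene–environment interaction); **C** (c²) is
environment common to both members of a pair regardless of zygosity;
**E** (e²) is individual-specific environment and also absorbs
measurement error, which is why E can never be dropped from a candidate
model.  Heritability is the standardized proportion h² = a²/v.

**Estimation.**  The log-likelihood is the sum over pairs of the
bivariate-normal log density, computed in closed form per zygosity group
(2×2 determinant and quadratic form; no generic multivariate-normal
machinery in the hot path).  It is maximized over *path coefficients*
(a, c, e) and the means-model β; the variances are the squares of the
path coefficients, which enforces non-negativity without constrained
optimization.  The sign of a path coefficient is not identified, so the
reported estimates are absolute values.  Optimization is L-BFGS with
five starts: a Falconer-style moment estimate (a² = 2(rMZ−rDZ)·V,
c² = (2rDZ−rMZ)·V, e² = (1−rMZ)·V, floored and rescaled to the
phenotypic variance) plus four log-normal perturbations of it; the best
converged start is kept.  Boundary optima (â = 0 or ĉ = 0) are ordinary
and handled naturally by this parametrization.

**Means model.**  One intercept is shared across zygosity groups.
Covariates (chronological age in the shipped analyses) enter per
individual.  Because co-twins share their age, an age trend in the
phenotype contributes to the within-pair covariance of *both* zygosity
groups equally — i.e. it masquerades as C.  Adjusting the means model
for age therefore moves variance out of C and, mechanically, raises the
*standardized* h² of the residual variation.  The package exposes both
analyses; neither is privileged.

**Model selection.**  `select_model` fits ACE, AE, CE and E, tests each
reduction against ACE with the likelihood-ratio statistic
2·(logL_ACE − logL_reduced) on df = number of dropped components, and
chooses the minimum-AIC model among ACE and the reductions not rejected
at α = 0.05.  The chi-square reference is used as-is: when a variance
component sits on the boundary of its parameter space the plain
chi-square is conservative (the asymptotic null is a 50:50 mixture of
χ²₀ and χ²₁), and we document and test that conservativeness (observed
type-I rate ≈ 3% at nominal 5%) rather than correcting for it, keeping
the procedure the simple textbook one.  AIC ties within 1e-9 go to the
model with fewer parameters.

**Uncertainty.**  Standard errors for the standardized proportions come
from the delta method on a central-difference Hessian of the
log-likelihood at the optimum, with a pseudo-inverse so that boundary
fits (singular curvature in a path coefficient at zero) still yield
intervals; intervals are clipped to [0, 1] and should be read as
approximate near a boundary.  These CIs are an additive diagnostic of
this package, not part of the original analysis procedure it follows.

**Intrapair correlations** are double-entry Pearson correlations (each
pair contributes both orderings), computed from symmetric sufficient
statistics so the value is bit-identical under arbitrary within-pair
relabelling.

## The glycan clock

Glycan age is quadratic in one primary peak percentage and linear in two
secondary peaks.  Both published coefficient sets are frozen constants
(`CROSS_SECTIONAL_CLOCK`, `LONGITUDINAL_CLOCK`); the two cohorts were
integrated into 24 vs 22 chromatogram peaks, hence the different peak
names (GP6/GP14/GP15 vs GP4/GP12/GP13).  No structural mapping between
the two integrations is attempted — none is defined — so the choice is
purely peak-name configuration.  `fit_clock` re-estimates the five
coefficients by OLS of age on [1, p, p², s₁, s₂] using one twin per
pair; the kept member is drawn uniformly per pair with a seed (a
deterministic "first by sample id" rule is available for audits).
Clocks are fit and scored on percent-scale values exactly as produced by
the preprocessing chain, with no re-normalization after batch
correction.

## Preprocessing

Raw areas → percent (divide by row total, ×100) → natural log →
batch correction → exp.  The log base is a free choice (any base is
equivalent up to a rescaling absorbed by a clock refit); natural log is
used so that exp restores percentages exactly.  After correction the
rows no longer sum to exactly 100; the values are used as-is.

Batch correction is the parametric empirical-Bayes location/scale model
of Johnson, Li & Rabinovic (2007), implemented from scratch with peaks
as features and no covariates in the batch design: per-peak
standardization against the batch-size-weighted grand mean and pooled
within-batch variance; per-batch location effects γ shrunk toward a
normal prior and scale effects δ² toward an inverse-gamma prior, with
hyperparameters by method of moments across peaks and the posterior pair
(γ*, δ²*) solved by fixed-point iteration (tolerance 1e-6, max 500
iterations; non-convergence raises, never passes silently).  The
implementation agrees with the Bioconductor reference (`sva::ComBat`) to
~1e-6 on test fixtures.  Two consequences of the empirical-Bayes
shrinkage are worth stating because they bound what "corrected" means:
residual between-batch mean differences of order sd/√n_b remain after
correction, and per-peak grand means move slightly (shrinkage ×
posterior-scale division), so the pipeline's guarantee is a large
*reduction* of batch structure (tested as a strict decrease of every
peak's between-batch F statistic), not its exact elimination.  A single
batch is returned unchanged with a warning; a batch with one sample is
an error (its scale effect is not estimable).

## The synthetic-data generator

The generator emulates the study conditions the estimators are meant to
face: 479 MZ + 1193 DZ pairs (3344 individuals) in the cross-sectional
design and 549 + 1201 pairs over three time points in the longitudinal
one, with inter-visit gaps drawn Normal(7.5, 3.27²) and Normal(6, 2.5²)
years.  The A/C/E construction is exact: MZ co-twins share one
standard-normal A draw, DZ co-twins get A = √½·A_common + √½·A_unique,
C is one draw per pair, E one per individual; within-pair covariances
are therefore a²+c² (MZ) and ½a²+c² (DZ) by construction.  Across
longitudinal time points A and C persist (same genome, same household)
while E is redrawn per visit, matching the package's choice to fit each
time point independently.

Defaults that are the package's own choices (the source analyses do not
state them):

- **Phenotype scale**: glycan-age mean 55 y, total variance 16 y²
  (SD 4 y) split 39/45/16% into a²/c²/e².  The split mirrors the
  variance decomposition the cross-sectional analysis reports; the SD is
  a realistic within-cohort dispersion of a clock after removing the
  mean age trend.
- **`age_beta` = 0 by default**: the planted (a², c², e²) are then
  exactly the phenotype's variance components, so recovery tests have
  exact ground truth.  Because co-twins share their age, any nonzero age
  trend adds β²·Var(age) to the C-like covariance; the age-confounding
  scenarios used in the covariate-adjustment tests set `age_beta > 0`
  explicitly.
- **Peak composition**: secondary predictor peaks are truncated normals,
  TN(8, 1.5²) and TN(2, 0.5²) percent; the non-predictor peaks are a
  symmetric Dirichlet (concentration 20) rescaled so every sample sums
  to exactly 100%.  These put the attainable glycan-age band of the
  clock inversion (see below) over the default target range.
- **Batch effects**: 4 batches, additive log-scale shifts
  Normal(0, 0.1²), multiplicative log-scale factors log-normal with
  log-SD 0.05 (positivity guaranteed), total areas Uniform(8·10⁴,
  1.2·10⁵) arbitrary units — moderate technical variation of the kind
  the ComBat step exists to remove.

**Clock inversion.**  Given a target glycan age t and drawn secondaries,
the primary peak solves the quadratic on its *ascending branch* (below
the vertex at −b₁/(2b₂) ≈ 9 percent), keeping the peak in a realistic
0–10% range.  A target is attainable iff the polynomial's value at
p = 0 lies within [t − h, t], where h = b₁²/(4|b₂|) ≈ 23.7 y is the
vertex height — an interval that depends on the secondaries only through
their linear contribution.  Secondaries are rejection-sampled up to 50
times; the rare residual cases are completed deterministically by
drawing that contribution uniformly from the exactly attainable
interval, so inversion succeeds for every target below the polynomial's
global maximum and the round trip through the clock reproduces targets
to 1e-9 years.  Truly unattainable targets raise an error.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: chromatogram traces and peak-integration
error, non-normal phenotype tails, assortative mating, gene–environment
correlation or interaction, dominance (ADE worlds), sex effects (the
emulated design is all-female), missing-at-random dropout, and co-twins
measured in the same batch (batches are assigned per sample,
independently of pairing — batch noise is E-like by design, where a
pair-shared batch would inflate C).

## Numerical choices and degenerate inputs

- Likelihood: invalid covariances (v ≤ 0 or |ρ| ≥ v, e.g. e = 0 with A
  or C free) yield −∞ inside the optimizer and a validation error in the
  public `pair_loglik`.
- L-BFGS tolerances `ftol` 1e-13 / `gtol` 1e-9; the acceptance oracle
  check holds the maximized log-likelihood to within 1e-3 of a
  brute-force grid refined to 1e-3 steps.
- A and C are not separately identifiable from a single zygosity group;
  such fits raise immediately rather than returning a ridge.
- Pairs must be complete: singleton exclusion happens per time point
  (a co-twin must be measured at the same visit), and dataset
  construction from long-format tables rejects incomplete pairs.
- Test problem sizes: Monte-Carlo covariance checks use 20000 pairs per
  zygosity (tolerance ±0.02); recovery and selection-consistency suites
  use 100 replicates at the study's design sizes; the LRT calibration
  bound uses 500 replicates; the likelihood-vs-grid oracle uses 20
  datasets of ≤ 200 pairs.

## Known limitations

- The delta-method CIs are asymptotic and approximate near boundaries;
  no profile-likelihood or bootstrap intervals are provided.
- No ADE (dominance) models, sex-limitation models, or longitudinal
  covariance structure across time points (each visit is fit
  independently).
- The LRT uses the plain chi-square reference by design (conservative at
  boundaries, as documented above).
- Batch correction supports the parametric variant only; no
  non-parametric or reference-batch mode, and no covariates in the batch
  design.
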