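# Methods

## Scope and model

`morphomod` analyses 3D cranial landmark configurations from pairs of
wild and domesticated mammal populations. The scientific question it
serves is whether the cranium is organised into covariance modules that
track the embryonic tissue origin of its bones — a neural-crest-derived
(NC) module and a mesoderm-derived (MD) module — and whether
domestication changed the disparity and integration of those modules.
The package takes no position on that question; it provides the
statistical machinery and a synthetic generator so that every stage can
be validated against known ground truth.

The analysis chain is: generalized Procrustes superimposition → symmetric
component of shape → allometry (shape-on-size regression) → covariation
and disparity statistics on both the uncorrected shapes and the
allometric residuals, always per pair (datasets are never pooled across
pairs).

## Superimposition and symmetry

GPA centres every configuration, scales it to unit centroid size, and
iteratively rotates it onto the running consensus by orthogonal
Procrustes rotation. Rotations are constrained to determinant +1; if a
reflected fit would be dramatically (10×) better than any rotation — the
signature of a specimen digitised with left and right swapped — the fit
aborts with an error instead of silently reflecting. Convergence is
declared when the root-mean-square change of the consensus drops below
`tol` (default 1e-10). The iteration cap defaults to 1000: sets of very
dissimilar shapes (e.g. random configurations in tests) converge
geometrically with a ratio near 0.96 and can need a few hundred
iterations, while real cranial data converges in under ten. No
tangent-space projection is applied; statistics operate on Procrustes
coordinates directly.

For object symmetry, each configuration is reflected, its paired
landmark labels swapped, and the 2n originals-plus-mirrors are
superimposed in one joint GPA. The per-specimen average of its two
copies is the symmetric component; the half-difference is the
asymmetric component, and the two add back exactly to the jointly
aligned original. The reflection axis (default y) is only a labelling
convention: any mirror produces the same symmetric component up to
rotation, and the midline-drift warning is therefore computed from the
asymmetric deviations of midline landmarks, not from their coordinate on
any fixed plane.

Modules are always taken as landmark subsets of the joint superimposition
(simultaneous-fit-then-subset); re-fitting a module separately changes
its coordinates and would break cross-module comparability. Per-group
statistics likewise subset the joint fit by specimen.

## Allometry

Shape (all 3p coordinates jointly) is regressed on natural log centroid
size. R² is SS_model/SS_total summed over all coordinates. Significance
uses residual randomization (RRPP) with the intercept-only model as the
reduced model: its residuals are permuted among specimens and the model
SS recomputed, with the observed arrangement counted among the `n_perm`
iterations, so p ≥ 1/n_perm. The allometry-corrected branch uses the
residuals of the pooled per-pair fit (grand mean added back by default).
Per-group allometric vectors are compared by the angle between them,
with an RRPP null built from the common-slope model. Centroid sizes are
compared with Welch's t-test on the log scale.

## Covariation statistics

**Covariance ratio (CR).** From the coordinate covariance matrix S
partitioned by module, CR = ‖S12‖F / √(‖S11°‖F · ‖S22°‖F), where °
zeroes the variable diagonal inside each within-module block. CR < 1
means more covariation within modules than between. The permutation null
reassigns whole landmarks (x, y, z together) to modules of the observed
sizes; the test is left-tailed. Because the full covariance matrix is
invariant under this permutation, it is computed once and each
permutation only re-sums a p × p matrix of squared 3×3-block norms —
this makes the test effectively free at any `n_perm`. CR never inverts
a matrix and is well defined on rank-deficient (n ≪ 3p) data.

Small-sample geometry note: with v variables per module, the
diagonal-exclusion denominator makes the large-n CR limit
(1 − 1/p_module)^(−1/2) ≈ 1 + 1/(2 p_module) under exactly exchangeable
correlation, so the "CR ≈ 1 when non-modular" calibration is checked
with 20+ landmarks per module, where the offset is ~0.025.

**Two-block PLS.** SVD of the between-block covariance of the centred NC
and MD blocks; r-PLS is the Pearson correlation of the first pair of
scores. The null permutes specimen rows of one block (right-tailed).
The effect size z standardizes the observed r against the raw
permutation distribution (no Fisher transform by default; the transform
is one flag away). Because each z is already a standardized deviate with
unit standard error, the pairwise comparison between analyses uses
(z₁ − z₂)/√2 with a two-sided normal p.

**Eigenvalue dispersion.** The relative standard deviation of the
eigenvalues of the module's 3·p_module-variable correlation matrix:
popSD(λ)/√(N_var − 1). It is 0 for the identity matrix, 1 for the
all-ones matrix, and exactly ρ for an exchangeable matrix — a
trait-count-independent integration measure, so no further division by
landmark count is applied.

## Disparity

Procrustes variance is the trace of the group covariance matrix with the
1/n divisor (not n − 1), matching the convention of the disparity
estimator this mirrors; PCA eigenvalues use the same divisor so that
they sum to total Procrustes variance and module traces add exactly to
the whole-cranium trace. Group contrasts permute group-mean-centred
residual vectors among specimens and compare |ΔPV|, observed counted.
For NC-vs-MD comparison, module disparities are divided by the module's
landmark count (p_module, not 3·p_module; the choice cancels in any
ratio or comparison).

## Cross-pair statistics

Eigenvalue dispersions across pairs are contrasted with paired t-tests:
NC vs MD over all pair × form combinations, NC vs MD within each form,
and wild vs domestic within each module. The disparity~integration
regressions are OLS with a form (wild/domestic) interaction over
pair × form × module observations, reporting per-form slopes, the
interaction F (full vs common-slope model) with both degrees of freedom
printed explicitly, and the variance-ratio F test between the forms'
disparity values. The PC1–PLS1 alignment is reported as |r| (axis signs
are arbitrary) for both blocks' scores.

## Synthetic generator

`simulate_dataset` builds bilaterally symmetric templates (paired
landmarks mirrored across y = 0, midline landmarks on the plane; NC
rostral, MD caudal) and adds, per specimen:

* a symmetric shape deviation drawn from a block-structured normal —
  one draw per bilateral pair, mirrored to both sides, with landmark-level
  correlation ρ_within_NC / ρ_within_MD / ρ_between and the three axes
  independent (covariance C ⊗ I₃, PSD-checked at construction);
* an allometric displacement along a fixed symmetric unit vector times
  (log size − mean);
* a symmetric mean offset for the domestic group and a dispersion
  multiplier on its deviations;
* small antisymmetric noise (default SD 0.005; with exactly zero
  asymmetry the symmetric-component midline coordinates are constant and
  correlation-based statistics would be degenerate);
* a random rigid motion and scaling to exp(log size), so raw files
  exercise the full superimposition path.

`simulate_block_normal` draws the same block-structured deviations
directly as flat matrices; it is the statistic-level counterpart used
for calibration, type-I and recovery checks where the geometric wrapping
would only add noise.

Defaults emulate the study conditions: `paperlike_presets()` carries the
six pairs' sample sizes (41/22, 45/25, 22/28, 133/83, 18/86, 14/21) and
landmark counts (60, 26, 62 × 4), moderate modular structure
(ρ = 0.3/0.45/0.15) with MD more integrated than NC, a domestic
disparity scale of 1.3 for all pairs except the horse pair (whose
domestic disparity was not elevated), group log-size offsets, and an
allometric vector norm of 0.75 with log-size SD 0.08, which places the
allometric variance share in the reported 6–23% range.
`strong_signal_params()` (ρ_within = 0.6, ρ_between = 0.25, n = 50 per
group) is the preset for power checks: strongly modular yet with an
unambiguous between-module association.

What the generator does **not** emulate: anatomically realistic cranial
geometry, measurement error structure of a digitizer, growth, or
non-Gaussian shape variation. Passing tests therefore demonstrate the
correctness and calibration of the estimators under the assumed model,
not the biological conclusions obtainable from real specimens.

## Numerical choices and degenerate inputs

* All permutation engines take explicit seeds; every stage seed in the
  pipeline is derived from one run seed via `SeedSequence`, so identical
  configurations reproduce bit-identically.
* Observed arrangements are always counted in permutation distributions
  (p ∈ [1/n_perm, 1]).
* Disparity recovery is exact only in the small-deviation regime: at a
  per-coordinate deviation SD of 0.02 with a 2× group scale, unit-size
  rescaling attenuates the disparity ratio by about 6% (shape-space
  nonlinearity); at SD 0.005 the attenuation is negligible, and the
  recovery checks run there.
* Degenerate inputs raise informative errors rather than propagating
  NaNs: coincident landmarks, constant log size, zero-variance
  coordinate variables (named by landmark and axis), single-group
  datasets, modules with fewer than two landmarks, zero within-module
  covariance.

## Problem sizes in the test and acceptance runs

The committed suite runs the type-I check at 200 replicates × 199
permutations (n = 50, 20 landmarks per module), the power check at 100
replicates of the full pipeline (n = 100, 30 landmarks), recovery at
n = 1000 specimens, and the six study-style presets at 1000
permutations; the whole suite completes in under a minute on one CPU,
the acceptance script in under a minute as well.

## Known limitations

* Only two modules are supported behaviourally (the CR machinery is
  structured for more but untested beyond two).
* Matching (paired-structure) symmetry, semilandmark sliding, 2D data
  and missing-landmark imputation are out of scope.
* The per-form PLS uses the joint pair fit subset by group rather than a
  per-form GPA; with large between-form mean differences these are not
  identical analyses.
* The F-test of disparity variances between forms assumes approximate
  normality of per-module disparities across pairs; with six pairs this
  is a coarse instrument.
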