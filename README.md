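# morphomod

Landmark-based modularity, integration and disparity analysis for
wild/domestic cranial shape comparisons.

## What this is for

A recurring question in evolutionary morphology is whether the mammalian
cranium is organised into **covariance modules** that follow the
embryonic tissue origin of its bones — elements derived from **neural
crest** cells (NC) versus those derived from **mesoderm** (MD) — and
whether domestication altered the variational properties of those
modules. Answering it requires a chain of geometric-morphometric and
permutation statistics applied per wild/domestic pair. `morphomod`
implements that chain as a tested, reusable Python library with a thin
CLI, aimed at morphometricians who have 3D landmark data, an a-priori
landmark→module map, and a bilateral landmark pairing.

The pipeline, per pair:

1. **Generalized Procrustes Analysis (GPA)** — iterative translation,
   unit-centroid-size scaling and rotation (det +1 only) onto a
   consensus; centroid size CS = √Σᵢ‖xᵢ − x̄‖².
2. **Symmetric component of shape** — each configuration and its
   mirrored, relabelled copy are superimposed jointly; the per-specimen
   average removes left/right asymmetry.
3. **Allometry** — multivariate regression of shape on log CS with
   residual-randomization (RRPP) significance; all downstream statistics
   run on both the uncorrected shapes and the allometric residuals.
4. **Covariance ratio** CR = ‖S₁₂‖F / √(‖S₁₁°‖F‖S₂₂°‖F) (within-block
   diagonals excluded), tested against a landmark-relabelling null;
   CR < 1 ⇒ modular structure.
5. **Two-block PLS (singular warps)** — SVD of the between-module
   covariance; r-PLS is the correlation of the first score pair, with a
   row-permutation null and a standardized effect size z comparable
   across analyses.
6. **Eigenvalue dispersion** — relative SD of the eigenvalues of a
   module's correlation matrix, a trait-count-independent integration
   magnitude in [0, 1].
7. **Disparity** — Procrustes variance (trace of the group covariance,
   1/n divisor), landmark-count-corrected for cross-module comparison,
   with permutation contrasts.
8. **Cross-pair synthesis** — dispersion t-test contrasts, pairwise PLS
   effect-size z-tests, and disparity~integration regressions with a
   wild/domestic interaction.

A first-class **synthetic generator** produces bilaterally symmetric
landmark datasets with known block covariance, allometry, group offsets
and dispersion scaling, so every stage is testable without real
specimens.

## Worked example

```python
import morphomod as mm

params = mm.SyntheticParams(
    seed=42, n_wild=30, n_domestic=30,
    rho_within_nc=0.45, rho_within_md=0.45, rho_between=0.15,
    disparity_scale_domestic=1.5, allometric_norm=0.75, logsize_sd=0.08,
)
config = mm.PipelineConfig(synthetic=params, n_perm=999, seed=42)
report = mm.run_pair(config)

b = report["branches"]["corrected"]
print(f"allometry R^2 = {report['allometry']['r_squared']:.3f}  (p = {report['allometry']['p']:.3f})")
print(f"CR = {b['modularity']['CR']:.3f}  (p = {b['modularity']['p']:.3f})")
print(f"r-PLS = {b['pls']['r_pls']:.3f}  (p = {b['pls']['p']:.3f}, z = {b['pls']['z']:.2f})")
print(f"dispersion NC/MD (wild) = {b['dispersion']['wild']['NC']:.3f} / {b['dispersion']['wild']['MD']:.3f}")
```

prints

```
allometry R^2 = 0.088  (p = 0.001)
CR = 0.720  (p = 0.001)
r-PLS = 0.765  (p = 0.001, z = 4.15)
dispersion NC/MD (wild) = 0.251 / 0.269
```

Reading: about 9% of shape variance is allometric and the effect is
significant; CR well below 1 with a left-tail p of 0.001 supports the
NC/MD modular partition the data were generated with; the modules are
nevertheless significantly integrated (r-PLS 0.77); and MD shows a
slightly higher integration magnitude than NC — all as built into the
generating parameters. The same `run_pair` report carries the
uncorrected branch, per-form PLS, per-module disparities with
permutation p-values, and the PCA/PLS1 alignment correlations.

With files instead of a preset:

```sh
morphomod simulate --seed 2 --out data/          # or bring your own files
morphomod run-pair --landmarks data/landmarks.csv \
    --module-map data/module_map.csv --pairing data/pairing.csv \
    --n-perm 999 --seed 2
morphomod run-study --seed 1 --out results/      # six study-style presets
```

Accepted formats: CSV wide (`LMi_x,LMi_y,LMi_z` columns), CSV long, and
TPS (`LM3=` blocks, read-only); module maps and symmetry pairings are
two-column CSVs with 1-based landmark numbers.

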