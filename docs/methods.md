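# Methods

## Model

blupcg solves multi-trait linear mixed models of the form
`y = Xf + Zu + e` through Henderson's mixed model equations (MME).  Each
random effect `u_k` has prior covariance `K_k ⊗ G₀_k`, where `K_k` is a
relationship matrix over the effect's levels (identity, pedigree `A`,
genomic `G`, single-step hybrid `H`, or user supplied) and `G₀_k` is the
covariance across the effect's per-level coefficients and traits.
Residuals are `e ~ N(0, D ⊗ R_c)` with one t×t residual covariance `R_c`
per residual class and `D = diag(1/wⱼ)` — a record's weight multiplies the
inverse of its residual covariance, the convention used for de-regressed
pseudo-phenotypes.  Records may observe any non-empty subset of traits;
the residual covariance is restricted to the observed traits *before*
inversion, which is the exact marginal likelihood treatment under joint
normality.

Equation ordering is trait-consecutive: within an effect, equations are
level-major, then regression coefficient, with the trait index innermost.
All cross-trait coupling of one (level, coefficient) pair is therefore a
contiguous t×t block, which is what the preconditioner exploits.

### Relationship matrices

- `A⁻¹` is assembled directly from Henderson's rules with inbreeding;
  inbreeding coefficients come from Meuwissen–Luo ancestor tracing, so
  inbred loops are exact.  A dense tabular-method `A` exists as a test
  oracle and for slicing `A22` (the genotyped block) at desk scale.
- `G` is VanRaden method 1 with allele frequencies observed from the
  genotyped set itself; missing genotypes are imputed to the locus mean
  `2pⱼ`, which preserves column centering and hence `G·1 = 0`.
- Invertibility safeguards: optional diagonal loading `G + λI`
  (parameter-file `diag_load`, e.g. 0.01) and/or a nearest-positive-
  definite projection (alternating symmetrisation and eigenvalue clipping
  with a floor, default `1e-8`; stop when the iterate moves < `1e-10` in
  Frobenius norm or after 100 sweeps).  For an already-symmetric input the
  first sweep is the exact Frobenius-norm projection.  The projection is
  applied before blending; the blend solves the 2×2 system matching the
  diagonal and off-diagonal averages of `G` to those of `A22`
  (`G* = βG + α`).
- `H⁻¹ = A⁻¹ + [τ((1−w)G* + wA22)⁻¹ − ωA22⁻¹]` on the genotyped block.
  `τ` and `ω` scale the genomic and pedigree information; `w` mixes a
  residual-polygenic share of `A22` into the genomic term.  Defaults are
  `τ = 1, w = 0, ω = 1` (the classical single-step inverse); the formula
  is implemented literally for any user-supplied values.

## Solver

The coefficient matrix is applied, never stored (iteration on data):

- least-squares part: per record, `t₁ = Wⱼ'd`, `t₂ = Rⱼ⁻¹t₁`,
  `tⱼ = Wⱼt₂` (right to left).  Internally the per-record designs are
  stacked into one sparse design and a block-diagonal `R⁻¹`, so a worker's
  record range is a contiguous row slice;
- random part per effect: `s₁ = (I ⊗ G₀⁻¹)d`, then `s = (K⁻¹ ⊗ I)s₁`.

PCG uses the classical Hestenes–Stiefel recursions with `x₀ = 0` (so the
convergence value starts at exactly 1), one coefficient product and one
preconditioner application per round.  The convergence value is
`c = ‖b − Cx‖₂ / ‖b‖₂`, tracked through the residual recursion
`r ← r − α v` and replaced by the exact `r = b − Cx` every
`refresh_interval` rounds (default 100) to purge accumulated rounding
error; the recursion/exact gap at each refresh is recorded for
diagnostics.  Defaults: tolerance `1e-13`, `max_rounds` 5000.

The preconditioner `M` holds the t×t trait-diagonal blocks of `C` — the
per-record least-squares additions land only inside a block, and each
level of a random effect adds its diagonal kinship entry times the
coefficient-diagonal blocks of `G₀⁻¹`.  Coefficient cross-blocks of
random-regression effects stay in `C` only.  `M⁻¹` inverts each block;
exactly-zero blocks (equations with neither data nor prior, e.g. an
unobserved fixed level) are replaced by the identity so their solutions
remain 0, with a logged warning.  A singular nonzero block is an error
naming the effect and level.

### Parallel semantics

Worker counts select a partition: contiguous record ranges differing by at
most one record, and contiguous level ranges balanced by the nonzero
counts of the kinship-inverse rows (binary search + greedy, which attains
the brute-force minimax on small cases).  Partial sums are combined in
worker-index order, so runs are reproducible; solutions for 1–8 workers
agree to ~1e−10, which is the package's correctness contract for
parallelism rather than any particular runtime mechanism.

## Synthetic data

The generators produce exactly the covariance structure the MME assumes,
so the estimator can be validated in two independent ways: *exactly*
against a dense assembly/solve oracle, and *statistically* against the
simulated truth.

- Pedigrees: discrete generations of random matings; small founder pools
  create inbred loops.
- Genotypes: founder allele frequencies Uniform(0.05, 0.95), founder
  alleles Bernoulli(p), offspring by gene dropping (one allele per parent
  per locus).  This reproduces pedigree relatedness in expectation
  (parent–offspring genomic relationship ≈ 0.5) but has no linkage map,
  LD structure, selection or genotyping error — passing tests say nothing
  about those features of real data.
- Phenotypes: true genetic values drawn with covariance `K ⊗ G₀`
  (trait-consecutive ordering), residuals `R/w` with uniform weights in
  (0.5, 5), missing traits masked at 20 % with at least one trait kept.
  Defaults emulate a reduced-scale weighted three-trait GBLUP.
- Test-day records: per-animal genetic regression coefficients from
  `A ⊗ G₀` with a normalized Legendre basis of order 4, permanent-
  environment coefficients from `I ⊗ P` at order 3, a herd-test-date
  class effect, and per-period residual variances over four equal periods
  of the lactation (days 5–305).
- `random_mme_case` draws small random models (1–3 traits, fixed
  class/regression plus 1–2 random effects over the four kinship sources,
  missing traits, weights, residual classes) for the dual-route oracle
  tests; an overall mean and a full class effect are never drawn together,
  and the first records cover every fixed level with all traits observed,
  so the coefficient matrix is nonsingular and the dense comparison well
  posed.

The Legendre basis is normalized, `φ_k(x) = √((2k+1)/2) P_k(x)` on
standardized time `x ∈ [−1, 1]`; normalization only rescales the
regression-coefficient covariances, which are user inputs.

## Numerical choices and limitations

- All covariance matrices are validated SPD by Cholesky; inverses are
  verified by multiplication back to identity (1e-8).
- The dense MME oracle refuses systems above 3,000 equations; it exists
  for testing only.
- `M⁻¹` is held in memory throughout the solve; streaming it from disk
  each round would only matter far beyond the scales this package
  targets.
- `A22` is sliced from the dense tabular `A`, which caps single-step
  models at desk scale (a few thousand pedigree members); indirect A22
  algorithms for large pedigrees are out of scope.
- Blending requires `Avg(diag G) ≠ Avg(offdiag G)`; degenerate inputs
  raise rather than return an ill-conditioned rescaling.
- Test problem sizes (hundreds of individuals, hundreds of markers, ≤100
  random models per property run) were chosen so the full suite and the
  acceptance script each complete in well under a minute on one CPU while
  still exercising every code path; all quantities they check are
  scale-free error bounds, not scale-dependent estimates.
- Variance components are taken as known inputs; REML/Gibbs estimation,
  metafounders, unknown-parent groups, dominance/epistatic relationships
  and APY-style sparse G-inverse approximations are not implemented.
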