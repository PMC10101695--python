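# Methods

## Data model and preprocessing

Genotypes are diploid calls at biallelic markers over the alleles
{A,C,G,T}, stored canonically with the two alleles of a call sorted
lexicographically (`AG`, never `GA`). Missing calls are rejected at parse
time everywhere: the pipeline assumes a fully imputed matrix, and
imputation is out of scope. A single-symbol CSV cell (`A`) is read as the
homozygous call `AA` by default — common in inbred plant panels — and can
be disabled.

**Minor-allele frequency.** For each marker, MAF = min(f, 1−f) where f is
one allele's share of the 2n allele slots; constant markers have MAF 0.
The filter keeps a marker iff MAF is *strictly* greater than the
threshold, so `threshold=0` removes exactly the monomorphic markers and
`threshold=0.5` removes everything. MAF is computed on the full sample
(before any split); the resulting keep-mask is persisted, so a user who
prefers training-partition-only filtering can see precisely what was
applied.

**Encodings.** The additive encoding counts copies of the *minor* allele
(0/1/2), with 50/50 ties resolved by calling the lexicographically
smaller allele minor; the chosen polarity is recorded per marker and
reused verbatim when new samples are encoded for a previously trained
model. The one-hot encoding expands each marker into one column per
*observed* genotype class, ordered (hom-major, het, hom-minor); a marker
without observed heterozygotes yields a two-column block. Per-marker
feature importances aggregate one-hot blocks by the sum of absolute
column scores.

**Splits.** All three split types (train–validation–test,
cross-validation with a held-out test set, nested cross-validation) are
derived from a single permutation drawn from `numpy.random.default_rng(seed)`
— the PCG64 generator — followed by contiguous slicing. That
seed-to-stream mapping is part of the on-disk contract: a split is fully
described by (type, parameters, seed, n), and loading a persisted split
re-derives it and errors on any mismatch, which doubles as a tamper
check. Sizes use round-half-away-from-zero on the test fraction first,
then the validation fraction of the remainder; this is stable and
independent of evaluation order. Discrete traits get class-stratified
assignment (per-class shuffles interleaved round-robin); continuous
traits are split sample-wise without stratification. Indices are 0-based
(`index_base` attribute in the HDF5 store) and stored sorted.

## RR-BLUP

Model: y = μ1 + Zu + e with u ~ N(0, σ²ᵤI_m), e ~ N(0, σ²ₑI_n); Z is the
additive matrix column-centered by training means (no variance scaling).
Marginally y ~ N(μ1, σ²ᵤK + σ²ₑI) with K = ZZᵀ. The restricted likelihood
is profiled in δ = σ²ₑ/σ²ᵤ after projecting out the intercept with a
Helmert contrast and eigendecomposing the projected K once:

  −2·ℓ_R(δ) ∝ (n−1)·log Σᵢ wᵢ²/(λᵢ+δ) + Σᵢ log(λᵢ+δ),

minimized over log δ ∈ [−12, 12] by bounded scalar search (tolerance
1e−8 on log δ). Non-convergence raises with the optimizer diagnostics; a
constant phenotype is rejected up front. Effects use the dual form
û = Zᵀ(K+δI)⁻¹(y−μ̂) with the GLS intercept, which equals the primal
ridge solution (ZᵀZ+δI)⁻¹Zᵀ(y−ȳ) for any fixed δ — the test suite holds
the two routes to 1e−8 relative agreement.

Heritability is reported on the per-sample scale:
ĥ² = s²_g/(s²_g+σ²ₑ) with s²_g = σ²ᵤ·tr(K)/n, matching the simulator's
definition var(g)/var(y). On simulated data (n=500, m=200, 20 causal
markers) the estimator is approximately unbiased at h² ∈ {0.2, 0.5, 0.8}.

## Bayesian alphabet (Gibbs)

All variants share y = μ + Z_c β + e, residual σ²ₑ with a scaled-inv-χ²
prior, flat prior on μ. BayesA gives every marker its own scaled-inv-χ²
effect variance (ν_u = 5); BayesB adds an exclusion indicator with prior
probability π; BayesC uses one shared effect variance plus the indicator.
Indicators are sampled with the effect integrated out analytically.

Default priors are method-of-moments: the effect-variance prior mode is
set to 0.5·var(y)·h²₀/m with h²₀ = 0.5 (divided by 1−π for B/C so the
implied genetic variance is comparable when most markers are excluded),
and the residual prior mode to 0.5·var(y); ν_u = ν_e = 5. All are
overridable, and either variance can be frozen — BayesC with π = 0 and
both variances fixed converges to the ridge solution at λ = σ²ₑ/σ²ᵤ,
which the tests verify to a 0.05 max-abs tolerance at 20k iterations.

π is a fixed user parameter (default 0.95), not estimated; estimating it
is a straightforward extension but complicates the determinism story.
Default chain: 6,000 iterations, 1,000 burn-in, thinning 5 — sized for
desktop-scale data and fully configurable. Random draws are batched per
iteration in a fixed order (effect normals, indicator uniforms, variance
χ² draws, then the shared-variance and residual draws), so a chain is a
pure function of (data, variant, settings, seed) regardless of the
sampled path. Markers with zero dosage variance are skipped with zero
effect.

## Hyperparameter optimization

The suggester is a tree-structured Parzen estimator over the declared
space (categorical, integer, real; optional log scale). The first 10
suggestions are uniform random; afterwards the top ceil(0.25·k) of k
completed trials form the "good" group, per-dimension Gaussian mixtures
l(x) and g(x) are built over good and bad values (Scott-type bandwidth
std·n^(−1/5)), 24 candidates are drawn from l, and the candidate
maximizing Σ_dims [log l − log g] is suggested. Two numerical choices
matter in practice and are deliberate:

* the bandwidth floor anneals as width/√(k+1) — wide early exploration
  that tightens as evidence accumulates, which prevents the classic TPE
  failure mode of cloning the incumbent; and
* out-of-range candidate draws are resampled (up to 10 rounds) rather
  than clipped, avoiding probability mass piling up on the bounds.

Suggestions depend only on the completed-trial history and the seed, so
identical runs replay identical trial sequences. Failed trials are
excluded from the history; duplicate assignments (reals compared at 6
significant digits) are recorded but not re-evaluated and do not consume
budget, up to a retry cap of 10× the trial budget.

**Pruning.** After each validation fold (from the second onward), a trial
whose running mean is worse than the median of completed trials' running
means at the same fold is stopped. No pruning occurs before 5 trials have
completed. Because the suggester conditions on completed trials only, a
pruning event changes the subsequent suggestion stream relative to an
unpruned run; the runs coincide exactly up to the first pruning event,
which is what the test asserts. The objective defaults to validation MSE
(minimized) for continuous traits and Matthews correlation (maximized)
for discrete ones, both configurable.

**Final refit and evaluation.** The best configuration is refit on the
train+validation part of the outer split (the outer-fold training part
under nested CV) and evaluated exactly once on the test set; under nested
CV the search repeats per outer fold and test metrics are averaged. A
leakage audit asserts that no test index appears in any fold used during
search. Run directories are keyed by seed rather than wall-clock
timestamp so that identical invocations land in identical paths and can
be compared byte-for-byte; each run serializes its trials, best
parameters, final model (coefficients, encoding polarity, training
column means) and a reproducibility hash over the deterministic run
content (trial parameters and values, best parameters, test metrics —
wall-clock metadata excluded).

## Phenotype simulator

`simulate_genotypes` draws independent biallelic markers under
Hardy–Weinberg proportions with per-marker MAF uniform in a configurable
range — a fixture generator, intentionally free of linkage structure.
`simulate_phenotype` implements the additive LMM
y = μ + Z_cβ (+ Zu_bg) + ε:

1. causal markers drawn uniformly without replacement among polymorphic
   markers;
2. raw effects from gaussian, laplace or equal distributions;
3. optional polygenic background: i.i.d. effects on all markers, scaled
   so the background contributes 10% of the causal genetic variance
   (equivalent in distribution to a genomic-relationship random effect,
   but O(n·m) and exactly seed-reproducible);
4. noise scaled against the *empirical* var(g) so var(g)/(var(g)+var(ε))
   equals the target h² — realized heritability is then within sampling
   error (±0.05 at n = 1,000) of the target;
5. noise gaussian or mean-centered gamma (shape 2) for skewed traits;
6. optional quantile discretization (median split for 2 classes,
   terciles for 3).

h² = 0 is special-cased to pure noise (zero recorded effects), since the
noise-scaling ratio is undefined there. Ground truth (causal ids, effect
vector, genetic values, realized h², config, seed) is stored with the
phenotype, and the export embeds the config as `#` comments so a
simulation is self-describing and exactly regenerable.

**What the simulator does not emulate** — linkage disequilibrium,
population and family structure, epistasis, genotype-by-environment
interaction, correlated multi-trait architectures. Tests passing on this
generator therefore demonstrate correctness of the estimators under the
stated additive model and calibration of the machinery, not performance
on structured real populations, where LD between causal and typed
markers and relatedness-driven leakage across splits change the picture
substantially.

## Evaluation

Continuous: MSE, RMSE, MAE, R² (1−SSE/SST), explained variance, Pearson
r. Discrete: accuracy, macro-averaged F1, multi-class Matthews
correlation. Metrics undefined on degenerate inputs (constant truth or
predictions, single-class folds) are reported as missing with a warning
flag instead of raising, so batch summaries survive bad folds. Formulas
are delegated to scikit-learn and property-tested against hand-written
reference implementations on random vectors.

## Problem sizes in the test suite

The suite and acceptance script use desk-scale sizes chosen to keep the
Monte-Carlo error of each property well inside its tolerance: ridge
agreement at n=30, m=8 (20 instances); REML recovery at n=500, m=200
(20 seeds × 3 targets); the Gibbs limit at n=50, m=10 with 20k
iterations; simulator calibration at n=1,000; the permutation-null check
at n=60, m=30 with 20 permutations per model and 1,500-iteration chains
(the null property is chain-length independent); optimizer quality with
a 30-trial budget against a 1,000-point grid.

## Known limitations

* RR-BLUP and the Bayes samplers handle continuous traits only and
  refuse discrete ones; discrete traits go to the penalized logistic
  baselines.
* The Gibbs samplers are single-site and pure Python/NumPy: fine for
  thousands of markers at desk scale, not for biobank-scale data.
* `apply` (prediction with a stored model) supports the additive
  encoding only.
* No LD pruning, kinship-aware splitting or relationship-matrix leakage
  control; nested CV controls selection leakage, not relatedness
  leakage.
* Trial execution is sequential by design; parallel workers would need a
  different determinism contract.
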