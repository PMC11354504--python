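# Methods

## Setting and assumptions

mrkit implements two-sample Mendelian randomization: genetic variants serve
as instrumental variables for a binary exposure (chronic hepatitis B in the
motivating study), and causal effects on a binary outcome (stroke and its
subtypes) are estimated from two independent sets of GWAS summary
statistics. The instrumental-variable assumptions are the usual three:
instruments are associated with the exposure, independent of confounders,
and affect the outcome only through the exposure. The estimators differ in
how much of the third assumption they relax: IVW assumes it for every
instrument, MR-Egger allows a common directional pleiotropic effect (the
intercept), and the weighted median tolerates invalid instruments carrying
up to half of the weight.

All effects are kept internally on the log-odds scale; odds-ratio columns in
input files are converted at parse time. Coordinates are 1-based. LD is the
signed correlation r, never r².

## Harmonization

Outcome effects are aligned per variant to the exposure's effect allele:
identical allele pairs are kept, swapped pairs negate the outcome beta and
complement its frequency, strand-complement pairs are recognized via reverse
complement, and anything irreconcilable is dropped with an audit record
rather than an exception. Palindromic variants (A/T, C/G) are strand
ambiguous; the default policy infers orientation by comparing both
effect-allele frequencies with 0.5 and drops the variant when either
frequency lies within 0.08 of 0.5 (a common two-sample MR convention,
configurable). None of the 12 packaged instruments is palindromic, so the
policy does not affect the motivating reproduction. Variants missing from
the outcome are dropped (never LD-proxied); standard errors are never
modified. The audit trail covers every input variant exactly once, which is
asserted as a property test.

## Instrument strength

F = R²(N−2)/(1−R²). Two R² formulas are exposed. The default, z-score form
R² = z²/(z²+N−2), makes F equal z² = (beta/se)² exactly and reproduces the
published per-variant F values of the motivating instrument table within a
few percent from the printed beta/SE (printing precision accounts for the
residual gap; e.g. a printed 0.113/0.023 limits z to ~2 significant
figures). The EAF form 2·EAF(1−EAF)·beta² is provided for completeness but
deviates several-fold from those published values, so it is not the default.
No exact equality with the published F column is claimed anywhere.

## Clumping

Greedy p-value-ranked clumping: keep the best remaining variant, prune every
remaining variant on the same chromosome within the window (pairwise
base-pair distance < window, default 10,000 kb) whose squared correlation
reaches the threshold (default r² ≥ 0.01). Ties in p are broken by
chromosome then position, so the output is a deterministic function of the
input set, invariant to row order. Variants absent from the LD matrix are
treated as uncorrelated and logged. The pipeline clumps after harmonization,
so an instrument missing from the outcome cannot become an index variant —
this ordering is what makes the motivating study's retained set
{rs1883832, rs7453920, rs9277535, rs1419881} reproducible.

## Estimators

Numerical routes, tolerances, and edge rules:

* Instruments with β̂_X = 0 are excluded with a warning before ratios are
  formed (the Wald ratio is undefined there).
* **IVW** is computed in closed form from the inverse-variance weights.
  With a single instrument it degenerates to the Wald ratio.
* **GLS forms** build Ω = D ρ D (D = diag(σ_Y)) and solve by Cholesky
  factorization. An optional ridge ε·diag(Ω) (default ε = 0) handles
  near-collinear panels; a condition-number guard at 10¹⁰ raises with advice
  rather than returning garbage. With identity LD both GLS forms reduce to
  their canonical counterparts to 1e-12, asserted in tests.
* **Orientation.** Egger regressions first orient every instrument to
  β̂_X > 0 by jointly negating both betas. For the GLS forms the
  orientation also conjugates Ω by the flip signs: ρ is defined relative to
  the stored effect alleles, so reorienting an allele flips the sign of its
  correlations. For the same reason the "joint sign-flip invariance" of the
  LD-aware estimators holds only when the supplied LD matrix is transformed
  consistently with the flip; the canonical estimators are unconditionally
  invariant.
* **Variance models.** `fixed` uses the model-based SE; the default
  `multiplicative_random` inflates it by max(1, √(Q/(J−1))) (residual df
  J−2 for Egger), matching prevailing two-sample MR software. The floor at 1
  means random-effects SEs never undercut fixed-effects ones. Q inside the
  inflation is exactly Cochran's Q about the fixed-effects estimate.
* **Intervals and p-values.** IVW and weighted median use the normal 1.96
  multiplier and normal p-values; Egger uses t quantiles with J−2 df for
  both slope and intercept (with J = 4 canonical instruments that is 2 df,
  hence the visibly wide Egger intervals).
* **Weighted median** uses the standard half-mass interpolation
  s_k = Σ_{i≤k} w'_(i) − w'_(k)/2 over the ordered ratios. Note the
  estimate equals a dominant (> 50 % weight) instrument's ratio exactly only
  when that instrument's half-mass point lands on 0.5 (e.g. symmetric
  flanking weights); in general the interpolation shades toward it. The SE
  is a parametric bootstrap (default 1000 replicates) resampling both betas
  from their reported normals and recomputing the median with recomputed
  weights; the seed is a required argument — there is no silent global RNG —
  so results are bit-reproducible.

Every estimator is checked against an independent brute-force oracle
(loop-summed normal equations, hand-coded elimination, direct matrix
inverse, Cholesky whitening + OLS, exhaustive median-crossing scan) to
1e-10 on random instances.

## Sensitivity analyses

Cochran's Q with J−1 df diagnoses heterogeneity; for correlated instrument
sets the generalized residual form rᵀΩ⁻¹r about the GLS estimate is used,
since the naive Q over correlated ratios has no chi-square reference. The
Egger intercept t-test (J−2 df) diagnoses directional pleiotropy. The
Bonferroni comparison is non-strict (p ≤ α/m): a p-value exactly at the
threshold is declared significant, which is the convention required to
reproduce a boundary call of p = 0.010 at threshold 0.01 in the motivating
study.

## Synthetic data generator

The generator draws MAF ~ U(maf_range), true instrument effects
γ ~ U(gamma_range), sets SEs by se = 1/√(2·maf(1−maf)·n_eff) with
n_eff = 4/(1/cases + 1/controls) for case/control cohorts (the
quantitative-trait formula with an effective-n mapping, since only
case/control counts are printed for the motivating GWASs), then forms

    β̂_X = γ + ε_X,   β̂_Y = θγ + α + ε_Y,

with ε_X, ε_Y independent draws from N(0, D R D) for the requested LD
matrix R, and α per the pleiotropy mode (none / balanced / directional).
Defaults are the motivating study's conditions: J = 12, exposure cohort
9114/9257, outcome cohort 27,413/237,242, and gamma_range (0.09, 0.20)
chosen so single-variant F-statistics span roughly 25–320, the range of the
packaged instrument table. One explicit numpy Generator per study makes
studies bit-identical per seed.

`paper_like_study` glues the packaged instrument table (taken verbatim as
the exposure side) to a simulated outcome with SEs scaled to the smallest
stroke-subtype cohort (1735 cases / 237,242 controls) and omits rs2853953 to
emulate its absence from the real outcome files. Its LD matrix is a
synthetic stand-in — three compound-symmetry blocks (r = 0.7) grouping the
chromosome-6 variants by physical position, plus the independent
chromosome-20 variant — built so that clumping at r² < 0.01 retains exactly
the four-instrument set of the real analysis. It reproduces that *retention
pattern*, not the panel's actual correlations, so headline effect estimates
on real outcome data require a user-supplied LD matrix.

What passing tests on these synthetics do and do not show: they validate
the estimators' algebra, calibration, and the pipeline's plumbing under the
generator's assumptions (normal errors, correctly specified SEs, no sample
overlap, no winner's curse, biallelic aligned variants). They do not
validate robustness to misreported SEs, population stratification, selection
effects, or allele-frequency mismatches between cohorts — real-data concerns
the generator deliberately does not model.

## Calibration experiment design

Two experiments deserve a note on their design, chosen so that the nominal
test is exactly calibrated under the generator rather than approximately so:

* the balanced-pleiotropy Egger type-I experiment fixes MAF at 0.3, making
  all outcome SEs equal; with heteroscedastic SEs and additive pleiotropy
  the inverse-variance weights are misspecified and the t-test is only
  approximately calibrated — a property of the design, not the estimator;
* the Q-uniformity experiment uses a large exposure cohort (n = 200,000) so
  weak-instrument noise in the weights does not distort the chi-square
  reference.

Monte-Carlo sizes (2000 replicates for rejection rates and uniformity, 500
for bias orderings, 200 for parameter recovery, 100 seeds for pipeline
coverage) were chosen to keep the whole suite around ten seconds on one
core while leaving rejection-rate tolerances at ±3 binomial SDs.

## Known limitations

* No LD-proxy lookup for instruments missing from the outcome; they are
  dropped, as in the motivating study's handling of rs2853953.
* No MR-PRESSO, mode-based, Steiger, multivariable, or leave-one-out
  methods; no I² statistic.
* The weighted median implements the inverse-variance-weighted variant
  only (no penalized or simple weighting).
* LD matrices are consumed, never estimated: computing r from genotype
  panels is out of scope.
* The effective-n SE approximation ignores case/control imbalance beyond
  the harmonic mean and ignores covariate adjustment in the source GWAS.
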