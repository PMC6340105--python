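# Methods

This note documents the statistical models, the numerical choices and the
synthetic-data conventions behind `penmates`, in the spirit of a model
reference rather than a user guide.

## Models

All three model classes are instances of one Gaussian mixed model for
average daily gain (ADG, g/day):

```
y = X b + Z_p p + Z_a a_D + S a_S + e
```

* `X b` — batch (reference-coded, intercept retained), initial age,
  final age and pigs-per-pen covariates.  The pigs-per-pen covariate is
  centred; this improves conditioning against the pen effects without
  changing inference.  If pen size is constant the covariate is dropped
  (it would be identically zero), with a warning.
* `p ~ N(0, I σ²_pen)` — shared non-genetic pen environment.
* `(a_D, a_S) ~ N(0, G ⊗ A)` — direct and social breeding values over
  the **whole pedigree**, with `A` the numerator relationship matrix.
  Effects are stacked effect-major (all `a_D`, then all `a_S`), so the
  prior precision is `G⁻¹ ⊗ A⁻¹`; animal-major stacking (`A ⊗ G`) is the
  same distribution, only an index permutation.
* `S` — social incidence.  `AM`: absent.  `AM_IGE`: 0/1 pen-sharing
  (each record row carries `n−1` ones).  `AM_IGE_i`: row entries are the
  animal's standardized behaviour distances `c_ij` to its pen mates.
* `e ~ N(0, I σ²_e)`.

### Interaction degrees

For a pair of pen mates, the degree is the Euclidean distance between
their standardized behaviour records — one trait (`|z_i − z_j|`) or all
four jointly (root sum of squared differences).  Two standardizations
are involved, both **global and population-SD (n denominator)**:

1. trait records are standardized across all phenotyped animals (a flag
   is not provided per pen; the global choice follows the definition of
   the degree as a property of the dataset's pair distribution);
2. raw distances are centred and scaled by the mean and SD over **all
   within-pen pairs in the dataset**, so the within-pen entries of `C`
   have mean 0 and SD 1 exactly.

Negative entries (pairs more alike than average) are retained as signed
coefficients; this is what makes evaluating `T²` at the quartiles of the
degree distribution meaningful.  Cross-pen and diagonal entries are
structural zeros.  An animal missing a required trait is a hard error by
default; an optional fallback assigns its whole pen classical 0/1
coefficients instead.

### Behaviour traits from feeder events

Daily traits from a visit stream: FF = visit count, OT = summed
duration, FR = intake/OT (undefined on zero-occupation days), FInt =
mean gap between the end of one visit and the start of the next within
the calendar day (undefined with fewer than two visits; across-midnight
gaps are never counted).  Visits are bucketed into 1-h blocks and
re-entries within the same block separated by less than one minute are
merged into a single visit — the standard editing step for single-space
electronic feeders, where brief displacements at the trough otherwise
inflate FF.  Aggregation to 2-week periods (or the whole fattening
window) averages the defined daily values only; absent animal-window
combinations stay missing rather than zero.

## Gibbs sampler

Single-site updates for fixed and pen effects and per-animal 2×2 block
updates for `(a_Di, a_Si)` (their full conditional couples through the
record design and through `A⁻¹` row i), in a fixed systematic scan; any
scan visiting every coordinate leaves the stated posterior invariant,
and the blocked genetic update substantially improves mixing over
scalar sites because direct and social effects of the same animal are
strongly correlated a posteriori.  Variance full conditionals under
flat priors: scaled inverse chi-square for σ²_pen and σ²_e (shape
`levels/2 − 1`), inverse Wishart `IW(q − 3, Sg)` for `G`, with
`Sg` the crossproduct of the genetic effects in the `A⁻¹` metric — the
`−3 = −(dim+1)` offset is the improper-flat-prior limit.  The
inverse-Wishart draw uses a Bartlett decomposition; numerically
non-positive-definite candidates are rejected (50 consecutive rejections
abort the run with diagnostics).

"Flat" variance priors are made proper by bounds `(0, 10⁶ × var(y))`;
draws above the bound are clamped and counted (a clamp indicates an
unidentified component, e.g. a social variance with an all-zero
incidence).  After a clamp, σ_DS is clipped into the PD cone.

The sweep kernel is numba-compiled; the residual vector is updated
incrementally and refreshed exactly every 2,000 sweeps to prevent
floating-point drift.  Chains are exactly reproducible from the seed.
The default protocol is 50,000 sweeps / 10,000 burn-in / thin 10 —
calibrated on the synthetic datasets used here, where it reproduces
EM-REML point estimates closely; the published-scale protocol
(3,000,000 / 300,000 / 10) is a configuration choice, not the default.

Derived parameters (h², genetic correlation, σ²_TBV, σ²_P, T²) are
computed **sample-wise along the chain** and then summarized; with
skewed variance posteriors this differs materially from plugging
posterior means into the formulas.

## EM-REML

The EM fixed point is the classical one for Henderson's mixed-model
equations: each iteration replaces every (co)variance by the expected
crossproduct of its effects given data and current values.  It is
evaluated in the marginal parameterization: with
`V = σ²_e I + σ²_pen Z_pZ_p' + Σ_uv G[u,v] W_u A W_v'` and
`P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹`,

```
G      ← G + G (Y − T) G / q         Y[u,v] = y'P W_u A W_v' P y
σ²_pen ← σ²_pen + σ²_pen² (y'P N_p P y − tr(P N_p)) / n_pen
σ²_e   ← σ²_e   + σ²_e²   (y'P P y   − tr(P))       / n
```

with `T[u,v] = tr(P W_u A W_v')` and `N_p = Z_pZ_p'`.  The `n×n` kernels
`W_u A W_v'` are precomputed once, so each iteration costs one `n×n`
Cholesky — independent of pedigree size.  Convergence: maximum relative
parameter change below 1e−6 (default), at most 500 iterations; a
non-converged run returns the last iterate, flagged.  Because EM crawls
along the weakly identified directions of the social model (σ_DS,
σ²_pen vs. σ²_S), the driver applies SQUAREM-style extrapolation by
default — two EM steps, a quadratic extrapolation, and a stabilizing EM
step; inadmissible extrapolants (non-PD `G`, negative variances) fall
back to the plain EM iterate, so the fixed point is unchanged.  With no
random effects the fixed point is the degrees-of-freedom-corrected OLS
residual variance, which the tests verify.

## Variance partitioning

At average interaction degree `c`, group size `n` and mean within-pen
relationship `r`:

```
σ²_TBV = σ²_D + 2c(n−1)σ_DS + c²(n−1)²σ²_S
σ²_P   = σ²_D + c²(n−1)σ²_S + r[2c(n−1)σ_DS + c²(n−1)(n−2)σ²_S]
         + σ²_pen + σ²_e
T²     = σ²_TBV / σ²_P
```

For the classical model `c = 1`; for pair-specific degrees the scale is
centred, so `c = 0` is the average interaction and the empirical Q1/Q3
of the within-pen `C` entries probe low- and high-competition pairs.
These forms insert the degree `c` wherever `n−1` multiplies a social
term in the equal-degree formulas; the pair-specific generalization is a
reconstruction consistent with that limit, and reports flag it as such.
`σ²_TBV` can fall below `σ²_D` when σ_DS < 0 — that negative covariance
is exactly what caps T² despite extra social variance.  Under
pair-specific degrees the total breeding value uses each animal's
realized column sum of `S` (its total expressed influence), which
reduces to `DBV + (n−1)·SBV` in the classical case.  `n` defaults to the
mean phenotyped pen size; `r` to the pedigree-computed mean within-pen
relationship.

## Model comparison

* **DIC** uses the conditional Gaussian deviance — conditioning on all
  location effects and σ²_e — matching the convention of the
  Gibbs-sampling software family standard in animal breeding;
  `pD = mean D − D(posterior means)`.
* **Cross-validation** is pen-stratified: each of k = 8 folds holds out
  one record per pen (57 pens → 57 held-out animals per fold).  Variance
  components are refit per fold at reduced chain length (the
  statistically clean choice; reusing full-data estimates is possible
  via configuration).  A held-out animal is predicted from fixed
  effects, its pen effect, its pedigree-propagated DBV and the
  coefficient-weighted SBVs of its mates; its interaction coefficients
  come from behaviour data, which is an input, not the response.  Pens
  with fewer records than folds contribute to only some folds, each
  record held out at most once.
* **Ranking agreement**: top-10% coincidence (ties broken by stable
  animal-id order, set size rounded, minimum 1) and Spearman/Pearson
  rank correlations, plus DBV/SBV/TBV component correlations over
  phenotyped animals.

## Synthetic data

The generator is the forward model itself, with stored truth, so
`y − Xb − Z_p p − Z_a a_D − S a_S = e` holds exactly.

* **Pedigree**: discrete generations, random mating (default 90
  founders, one intermediate generation of 250, final generation 663);
  genetic effects are drawn by pedigree recursion (parent average plus
  Mendelian sampling `N(0, φ_i G)`, `φ_i = 0.5 − 0.25(F_s + F_d)` with
  Meuwissen–Luo inbreeding), which realizes `G ⊗ A` without dense
  factorization.
* **Pens**: 57 pens of 10–14 (sizes randomized within bounds), filled
  70% family-wise (litter mates and half sibs penned together, as
  on-farm batching does) and 30% at random.  This one-time calibration
  puts the mean within-pen relationship near 0.13, the realistic level
  for a closed line with litter-structured housing — and the level at
  which the direct–social covariance is identifiable at all.
* **Behaviour**: per-period latent scores follow a stationary
  multivariate AR(1) with persistence 0.75 — consecutive-period rank
  correlations land in the observed 0.67–0.86 band — and
  cross-sectional correlations FR–FF 0.56, FR–OT −0.20, FR–FInt −0.60,
  FF–FInt −0.64, completed with FF–OT −0.25 and OT–FInt 0.15 (plausible
  signs for a dominance gradient) to a positive-definite matrix.  Trait
  means/SDs (FR 25±5 g/min, FF 12±4 visits, OT 80±18 min, FInt 60±20
  min) are conventions; only the correlation and persistence structure
  is a constrained target.  An optional renderer expands daily traits
  into an explicit visit stream (equal-length visits, FInt-spaced,
  intakes realizing FR) that round-trips through the trait derivation to
  within 1%.
* **Phenotypes**: true components default to σ²_D 0.46, σ²_S 0.004,
  genetic correlation −0.39, σ²_pen 0.12, σ²_e 0.40 — the plain-model
  heritability is then ≈0.47 of the ≈0.98 phenotypic variance.  Batch
  effects have SD 0.3; age/pen-size slopes are drawn uniformly from
  ±0.01 per unit.  The ADG scale is arbitrary (variances near 1); all
  reported parameters are scale-free ratios.

**What the generator does not emulate**: feeder-hardware error patterns
beyond the merge rule, circadian visit structure, non-Gaussian growth,
selection or non-random mating, pen-size confounding with management,
and any mean-level realism of the behaviour traits.  Passing tests
therefore demonstrate that the estimators recover the model's own
structure at realistic sizes, not that the model is adequate for any
particular real herd.

## Study sizes used in the tests

End-to-end checks run at deliberately reduced but realistic sizes: the
default 663-animal / 57-pen condition for parameter recovery (10 seeds,
50k-sweep chains), a 720-animal / 60-pen condition for the 10-replicate
EM-REML recovery study and the Bayes/REML concordance check, and a
240-animal / 24-pen condition with σ²_S = 0.05 ("strong IGE") for the
model-discrimination studies (DIC and cross-validation), where the
social signal is large enough for 20-replicate direction checks at short
chain lengths.

## Known limitations

* Single trait, single record per animal; no maternal or dominance
  effects, no genomic relationships.
* The conditional-deviance DIC penalizes location-level complexity only;
  a marginal DIC would rank differently in principle.
* EM-REML forms dense `n×n` kernels — fine to a few thousand records,
  not for national evaluations.
* The pair-specific `σ²_TBV`/`σ²_P` forms are a documented
  reconstruction (see above), exact in the classical limit.
* Flat variance priors with few levels (e.g. 57–60 pens) put the
  posterior mean of a variance visibly above its REML counterpart; the
  two estimators agree closely on correlations and on well-replicated
  components.
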