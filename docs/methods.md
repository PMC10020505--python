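# Methods

This package implements the per-regime analysis chain used to select tropical
maize hybrids evaluated in multi-environment trials (METs) under contrasting
soil-moisture regimes — optimal irrigation, managed drought, managed
waterlogging — and a synthetic trial generator that gives every stage a
testable ground truth.

## The mixed model and EM-REML

Within one regime, each trait is fitted with the linear mixed model

    y = X beta + Z u + eps

with fixed effects (beta): intercept, environment, replicate within
environment; random effects (u): genotype, genotype-by-environment
interaction (GEI), and incomplete block within replicate within environment;
residuals eps ~ N(0, sigma2_e I).  Environments absorb location and season.
The incomplete-block term is dropped automatically when every replicate holds
a single block (a complete-block design), where it would be confounded with
the fixed replicate effect.

Variance components are estimated by restricted maximum likelihood with the
expectation–maximization algorithm, computed on Henderson's mixed-model
equations (MME).  The restricted log-likelihood is evaluated each iteration
through the identity

    log|V| + log|X' V^-1 X| = (n - q - p) log sigma2_e
                              + sum_k q_k log sigma2_k + log|M|,

where M is the MME coefficient matrix; an O(n^3) dense evaluation of the same
quantity is kept as an independent oracle and checked in the tests.  EM for
variance components is monotone but slow near boundaries, so the implementation
wraps the EM map in a SQUAREM extrapolation (in log-variance space) that is
accepted only when the restricted log-likelihood does not decrease and falls
back to the plain EM iterate otherwise; the monotonicity contract is asserted
at every accepted step.  Convergence is declared when the restricted
log-likelihood changes by less than 1e-8 (default), with a cap of 500
applications of the EM map; a non-converged fit is returned with a warning
rather than an error.  Variance estimates are floored at 1e-10 and reported as
zero at the floor.

On balanced complete-block designs the EM-REML estimates coincide with the
ANOVA method-of-moments estimators, and with a general-purpose optimizer
maximizing the dense restricted likelihood, to 1e-6 — both are test oracles.

### Genetic parameters

With e environments and b replicates per environment:

* h2mg = sigma2_g / (sigma2_g + sigma2_ge/e + sigma2_e/(e*b)) — broad-sense
  heritability of a genotype mean.  b counts complete replicates (2 in the
  emulated trial); this is the replicate count of the source methodology even
  where "blocks" is the looser word used for it.
* selection accuracy As = sqrt(h2mg) — not an independent quantity; the
  reference tables are consistent with this identity in every internally
  checkable row except one known misprint (drought SPAD).
* sigma2_p = sigma2_g + sigma2_ge + sigma2_e.  The incomplete-block variance
  is deliberately excluded from the phenotypic total so that
  R2ge = sigma2_ge / sigma2_p matches the three-component construction of the
  reference variance tables.
* CVg = 100 sqrt(sigma2_g)/mean, CVr likewise from sigma2_e.
* The environment F statistic is a Wald-type quantity from the fixed-effect
  covariance block; it is approximate and never an acceptance surface.

### Likelihood-ratio tests

LRT for a random term refits the model without the term; the statistic
2(l_full − l_reduced) is clipped at zero and referred to the upper tail of
chi-square(1).  Because the null value sits on the boundary of the parameter
space this reference is conservative (empirical size below nominal — verified
by simulation); the 0.5*chi2(0) + 0.5*chi2(1) boundary mixture is available
via `boundary=True`.

### BLUP table

The two-way table feeding the index is X_ij = (mean of the fitted fixed part
of trait j) + BLUP of genotype i.  With zero genetic variance every entry
shrinks to the trait mean; as sigma2_e -> 0 the entries approach raw genotype
means.

## Genetic correlations

The genetic correlation between traits is the Pearson correlation of their
BLUP-based predicted genotype means (the convention of the source analysis
stack; a raw genotype-mean option exists behind a flag).  Trait proximity is
summarized by average-linkage hierarchical clustering on 1 − |r|, the tabular
replacement for correlation network figures.

## The MGIDI chain

1. **Rescaling.**  Each trait column of the BLUP table is mapped linearly to
   [0, 100] with 100 at the desirable extreme: max for increase-traits, min
   for decrease-traits (days to anthesis/silking and the anthesis–silking
   interval).  Being affine per column, rescaling preserves the absolute
   correlation structure exactly.
2. **Factor analysis.**  Principal-component extraction from the correlation
   matrix R of the rescaled table; f factors retained by the Kaiser rule
   (eigenvalues > 1, overridable); initial loadings eigenvector*sqrt(lambda);
   varimax rotation with Kaiser row normalization (SVD gradient-projection,
   criterion tolerance 1e-10, 1000 sweeps max).  Each rotated column is
   sign-flipped so its dominant loading is negative — a cosmetic convention
   matching the orientation of the reference loading tables; the index is
   provably invariant to column signs (asserted numerically to 1e-10).
3. **Scores.**  Z column-standardizes the rescaled table (sample SD, n−1);
   genotype scores F = Z R^-1 A; the ideotype — rescaled value 100 on every
   trait — passes through the same standardization and scoring map.  A
   singular R falls back to a ridge R + 1e-8 I with a warning.
4. **Index.**  MGIDI_i is the Euclidean distance between genotype i and the
   ideotype in factor-score space; the ideotype itself scores exactly zero.
   Selection keeps the round(g × intensity) lowest values
   (round-half-to-even: 75 × 0.15 → 11), ties at the cut broken by input
   order with a warning.
5. **Strengths/weaknesses.**  omega_ij = D_ij^2 / sum_j D_ij^2 with
   D_ij the per-factor genotype–ideotype gap; rows sum to one; a genotype
   exactly at the ideotype reports uniform 1/f with a flag.  Small omega on a
   factor means the factor's traits are near the ideotype.
6. **Gains.**  Per trait, SD% = 100 (Xs − Xo)/Xo with Xo the population mean
   and Xs the selected-set mean of the same BLUP-based table that feeds the
   index (whether the reference gains were computed on raw or predicted means
   is not recorded; both routes are available, BLUP-based is default).  Traits
   are attributed to the factor with their largest absolute rotated loading,
   ties to the lower factor index.

## Synthetic trials

The generator emulates the trial this analysis was designed for: 75 hybrids,
12 traits, seven environments (3 optimal, 2 drought, 2 waterlogging), two
replicates, five incomplete blocks per replicate.  Plot values are the sum of
trait mean, fixed environment effect, genotype effect, GEI effect, block
effect and residual.  Genotype effects are multivariate normal across traits
with correlation Lambda Lambda' + Psi induced by a three-factor loading
matrix (a vegetative/yield factor, a phenology factor, an ear factor);
uniquenesses Psi make the diagonal exactly one.

Default per-trait scales are taken from the optimal-regime summaries of the
reference trial: grand means, phenotypic variances, GEI shares R2ge and the
genotypic/residual CVs.  sigma2_g and sigma2_e derive from the CVs
(sigma2 = (CV*mean/100)^2) and sigma2_ge = R2ge * sigma2_p: these are always
mutually consistent, whereas inverting the printed h2mg is not for every
trait (the printed trio is over-determined and rounds inconsistently for,
e.g., grain yield).  Incomplete-block variance, unreported in the reference,
defaults to 5% of the residual variance.  Fixed environment effects are an
evenly spaced spread of ±0.4 phenotypic SD — deterministic given the config,
mirroring the fixed-effect treatment of environments.

The alpha-lattice layout is simplified to random allocation of genotypes into
equal incomplete blocks within each replicate (one smaller block when counts
do not divide); the variance structure, which is all that matters downstream,
is preserved, but the efficiency properties of a true (0,1) design are not
reproduced.  The generator does not model spatial field trend, stress-by-
management interactions or weather-driven growth — a green end-to-end test
establishes the statistical machinery, not field realism.

`spike_ideal_genotypes` shifts named genotypes' plots toward the ideotype by
a fixed amount; `spike_to_ideal` additionally neutralizes the genotype's own
random draw (known from the simulation truth) so it lands exactly k genetic
SD toward the ideotype on every trait — the controlled construction used by
the selection-power study, where an additive spike alone would be partially
cancelled by unlucky draws.

## Numerical and design choices

* EM start values: equal split of the sample variance across components.
* The SQUAREM extrapolation is clamped to ±8 natural-log units around the EM
  trajectory; a candidate that makes the MME matrix numerically singular is
  discarded in favor of the plain EM step.
* LRT reduced fits warm-start from the full-model components.
* Monotonicity assertions use a relative tolerance (1e-6 of |logL|) because
  near-degenerate fits (sigma2_e → 0) evaluate the likelihood with
  O(1/sigma2_e) quadratic terms and lose absolute precision.
* CSV round-trips write floats at 17 significant digits and parse with
  round-trip precision, so write→read is bit-identical.
* The analysis path contains no randomness; all stochasticity lives in the
  generator behind a single integer seed.

## Test-suite scaling

Simulation studies in the acceptance suite are sized to run on one CPU in
minutes: the LRT size study uses 500 replicates of a reduced design (20
genotypes, 3 environments); LRT power and parameter recovery use 100 and 50
replicates at full trial scale (75 genotypes, 3 environments, 2 replicates);
the end-to-end selection-power study uses 100 replicates of a 6-trait,
two-factor, 3-environment world rather than the full 12-trait default, whose
single-run behavior is covered by the pipeline tests and the acceptance
script.

## Known limitations

* The EM cap of 500 map applications can be reached for traits whose
  genotype variance sits near the boundary in two-environment regimes; the
  fit is returned with `converged=False` and a warning, matching the
  documented contract.
* The environment F statistic uses the estimated-variance Wald form without
  denominator-degree-of-freedom corrections.
* Genetic correlations from BLUP tables are attenuated toward zero at low
  heritability relative to the true genetic correlations; the generator's
  truth tables make this visible in tests.
* The printed reference tables carry occasional internal inconsistencies
  (one accuracy/heritability row, one gains row with swapped means, one
  garbled CV ratio); they are shipped verbatim where possible and documented
  in the data loader.
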