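# Methods

`twinherit` implements three estimators of the genetic architecture of a
binary trait in twin data — childlessness is the motivating phenotype —
together with a synthetic cohort generator that provides fully known
ground truth for all of them.

## Liability-threshold model

Every individual carries a latent standard-normal liability; the trait
is expressed when the liability exceeds a threshold τ fixed by the
prevalence K, τ = Φ⁻¹(1−K). Covariates shift the threshold linearly
(probit convention): member i of a pair is affected iff
liability_i > τ_sex(i) − β·(birth year − mean birth year).

Pair liabilities are bivariate normal with correlation composed from
variance proportions:

| component | MZ | same-sex DZ | opposite-sex |
|---|---|---|---|
| additive (a²) | 1 | 0.5 | r_g |
| shared environment (c²) | 1 | 1 | 1 |
| dominance (d²) | 1 | 0.25 | 0.25 |

For opposite-sex pairs the additive contribution is r_g·a_f·a_m, with
r_g playing the role of the same-sex DZ constant 0.5: r_g = 0.5 means
the same genes act in both sexes, r_g = 0 means sex-specific genes.
This matches the sex-limitation convention in which the fitted r_g
replaces, rather than multiplies, the DZ half-sharing factor.

### Fitting

`fit_twin_model` maximizes full-information likelihood: each complete
pair contributes the log of a bivariate-normal rectangle probability
(four outcome cells), each singleton a univariate tail probability.
Rectangle probabilities are evaluated through Owen's T function, which
is vectorized and accurate to ~1e-14; the four cell probabilities sum
to 1 to better than 1e-10, which the tests assert.

Variance proportions are parameterized as squared path coefficients
normalized to the simplex with the E coefficient pinned at 1, keeping
optimization unconstrained, smooth and strictly interior; r_g (when
free) is tanh-mapped to (−1, 1). Nelder-Mead runs from five
deterministic starting points and the winner is polished until an extra
restart improves −2LL by less than 1e-7. Profile-likelihood 95% CIs for
a² re-optimize all nuisance parameters at fixed a² and cut at
χ²₁(0.95) = 3.84; unlike Wald intervals they respect the [0, 1]
boundary.

Degrees of freedom are counted as observations (individuals) minus free
parameters *in this standardized parameterization*: one parameter per
free variance proportion, one threshold per sex present, one slope per
covariate, one for a free r_g. Equating the male and female AE
proportions therefore costs one degree of freedom; software that
parameterizes unstandardized paths books the same constraint as two.
Likelihood-ratio Δχ² and ΔAIC = Δχ² − 2Δdf are unaffected for the
comparisons reported here. AIC ties closer than 0.01 resolve toward the
more parsimonious model.

Singletons are retained through their marginal likelihood: they carry
no information about pair correlations but sharpen thresholds and the
birth-year slope, and it avoids discarding 27% of individuals in a
cohort with the default 43% singleton family share.

### Tetrachoric correlations

`tetrachoric` is a two-step estimator: thresholds are fixed at the
margin-implied normal quantiles, then ρ maximizes the multinomial
likelihood of the 2×2 table (bounded scalar minimization, tolerance
1e-6 on ρ). The two-step/full-ML difference is O(1/n) and invisible at
the table sizes used here; the CI is the ρ-profile likelihood at the
χ²₁ cutoff. Same-sex discordant pairs are split evenly between the two
off-diagonal cells (twin order is arbitrary); opposite-sex tables keep
the male-affected vs female-affected split, with member 1 the male.

## GREML

The joint model regresses the observed 0/1 outcome on fixed effects
(intercept, birth year, 20 GRM principal components) with two random
effects: cov = σ²_snp·IBS + σ²_extra·IBD + σ²_e·I. The IBS matrix is
the average over SNPs of products of standardized dosages
(entries (x_ij−2p_i)(x_ik−2p_i)/(2p_i(1−p_i)), pairwise-complete over
missing genotypes, allele frequencies taken from the post-QC analysis
sample). The IBD matrix copies the IBS matrix and zeroes off-diagonal
entries below 0.05, so it carries only within-family genome sharing;
σ²_snp is then identified by the relatedness variation among unrelated
pairs and σ²_extra by the family blocks, and their sum estimates
narrow-sense genetic variance.

Estimation is average-information REML: one EM-flavoured step, then AI
updates with step halving, variance components projected to a floor of
1e-6·var(y) (the genetic covariance in the bivariate model is left
unconstrained so it can go negative), convergence when the restricted
log-likelihood moves by < 1e-8, hard failure after 100 iterations.
The constrained refits behind the r_g = 0 and r_g = 1 likelihood-ratio
tests converge at 1e-5 instead — they only feed a test statistic of
order 1–100, where that precision is already three orders beyond the
chi-square tail's needs, and the r_g = 1 boundary fit otherwise crawls
through dozens of vanishing steps.
Standard errors come from the inverse AI matrix. The univariate fit is
verified in the tests against a brute-force restricted-likelihood grid
at n = 40 and against closed-form balanced-ANOVA estimators on
equicorrelated pair data.

Observed-scale heritabilities transform to the liability scale by
h²_liab = h²_obs · K(1−K)/z² · K(1−K)/(P(1−P)), z the normal density at
the threshold (K = P = 0.5 gives exactly π/2). Values above 1 are
returned uncapped with a warning.

The bivariate fit stacks two disjoint individual sets (men as trait 1,
women as trait 2), with block components vg1·G₁₁, vg2·G₂₂, cg·G₁₂ and
per-set residuals; the residual cross-covariance is structurally zero
because no individual carries both traits. r_g = cg/√(vg1·vg2), SE by
the delta method; r_g = 0 and r_g = 1 are likelihood-ratio tests
against constrained refits (the r_g = 1 refit reparameterizes
(vg1, vg2, cg) = (s₁², s₂², s₁s₂) and runs the same AI machinery
through the chain rule).

### Known property: liability transformation on family data

The observed-scale covariance of a threshold trait between relatives is
Φ₂(τ,τ;ρℓ) − K², which is convex in the liability correlation ρℓ; the
K(1−K)/z² transformation is its derivative at ρℓ = 0. At family-level
correlations it therefore overshoots: at K = 0.126 and a generating
liability h² of 0.59, the MZ-pair secant implies ≈0.85 and the DZ
secant ≈0.71 on the liability scale. A joint fit whose family
components dominate lands around 0.8 rather than 0.59, and the recovery
study and acceptance suite report exactly that (the corresponding check
is left failing rather than re-tuned). The bivariate genetic
*correlation* divides out most of this scale inflation and centres on
its generating value. For unrelated-sample designs — the setting the
transformation was derived for — the estimator is unbiased, which the
low-relatedness grid and ANOVA tests confirm.

## Polygenic scores

Clumping is greedy by ascending p (ties broken toward the smaller
position): accept the best remaining SNP, discard unaccepted SNPs on
the same chromosome within 250 kb or with dosage r² ≥ 0.1 against it
(r² computed on the analysis-sample dosages, pairwise-complete).
Scores sum effect-allele dosages weighted by the summary-statistic
betas over retained SNPs at each threshold (5e-8, 0.05, 0.5, 1);
alleles are reconciled by exact or swapped match (swap flips the beta
sign) and strand-ambiguous A/T, C/G SNPs are dropped with a count.
Scores are standardized on the final analysis sample — one member per
family, chosen deterministically (lowest id) or by seeded draw — after
that restriction. The interaction model,
outcome ~ PGS + sex + PGS×sex + birth year + education (women = 0,
men = 1), is a Newton/IRLS logistic fit (tolerance 1e-10; statsmodels
supplies the solver, verified in the tests against a likelihood grid).
Per-sex odds ratios derive from the fit: women carry the main effect,
the male OR is main × interaction with a summed-log-odds delta-method
CI. An empty genome-wide-significant score yields a notice row instead
of a model.

## Synthetic cohorts

Two generators share the study conditions as defaults: complete-pair
group sizes 513/814/513/549/1223 (female MZ/DZ, male MZ/DZ,
opposite-sex), prevalence 0.126 in women and 0.143 in men, birth years
uniform on 1911–1958 shared within pair, a 43% singleton family share
(one member dropped at random), homogeneous AE architecture with
a² = 0.474 and r_g = 0.

The path-coefficient generator draws pair liabilities directly from the
implied bivariate normal — it is exact for the twin model and needs no
genotypes. The genotype-driven generator simulates unlinked SNPs with
allele frequencies uniform on the MAF range through two parents per
family (MZ co-twins duplicate one child; sibs share half their alleles
in expectation), then builds liability = SNP score + family component +
residual: the score uses per-sex causal effect vectors correlated at
rg_snp, scaled to variance h²_snp within each sex, and the family
component is shared with pedigree correlation (1 MZ, 0.5 otherwise) to
stand for untyped additive variance. Summary statistics add noise with
SE 1/√(n·2p(1−p)) to true per-allele effects and report the two-sided
normal p.

Education is Gaussian (mean 11, sd 3, floored at 0) and independent of
liability by default; a coupling coefficient exists but the source
phenotype model never states one.

What the generator does *not* emulate — and hence what green tests do
not establish about real cohorts: linkage disequilibrium (clumping
exercises the distance rule on simulated data; the r² rule is tested on
constructed fixtures), assortative mating, genotyping error and
imputation uncertainty, X-chromosome dosage, ascertainment differing
from the population, and secular trends beyond a linear birth-year
threshold shift.

## Problem sizes and numerical choices

Recovery studies run at the sizes the estimators need, chosen once:
twin-model recovery at the full 3612 complete pairs (30 replicates);
joint-GREML recovery on ~2654-individual female cohorts with 5000 SNPs
(10 replicates); bivariate recovery on ~2980-individual mixed cohorts
(750 opposite-sex pairs plus 185 same-sex pairs per group, 20
replicates — r_g has a per-replicate sampling SD near 0.22, so this
study gets the extra replicates). The pipeline driver subsamples
families for its GREML stage (default cap 1200 individuals) because a
9942-individual dense REML is out of proportion for a demonstration
run.

All randomness flows from integer seeds through `numpy` SeedSequence
streams, one stream per stage; reruns are bit-identical. Bivariate
normal probabilities are clipped at 1e-300 before logs; REML declares a
boundary component below 1.01×10⁻⁶·var(y); monomorphic SNPs take HWE
p = 1 by convention and SNPs fixed in-sample are excluded from the GRM
with a warning. GRM PCA uses a Lanczos solver with a fixed start vector
for large matrices and dense eigendecomposition otherwise, with the
largest-magnitude loading of each component forced positive so signs
are reproducible.

## Limitations

- The liability-scale transformation of observed-scale GREML components
  is a first-order approximation that overshoots on related samples
  with a binary trait (quantified above); results from family-based
  binary GREML should be read as upper bounds.
- The twin model assumes equal environments across zygosity groups and
  no assortative mating; the generator builds both in by construction,
  so the tests cannot detect their violation.
- C and D are not simultaneously identifiable in univariate twin data
  and cannot both be requested.
- Two printed values in the source tables are internally inconsistent
  with their own inputs (the male-MZ concordances and the final
  E-model ΔAIC); the implementation reproduces the input-implied values
  and the test suite asserts the discrepancy rather than matching the
  prints.
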