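# Methods

## Disease-generating model

A dichotomous phenotype Y is generated from an additive odds model on the
log-odds scale. With g the total number of risk alleles carried across m
effect-allele positions (m/2 diploid risk SNPs),

    P(Y=1 | G=g) = logistic(β₀ + β g).

Under Hardy-Weinberg and linkage equilibrium with shared risk allele
frequency p_a, G ~ Binomial(m, p_a). The model's free parameters are the
prevalence K ∈ (0,1), the per-allele log odds ratio β (conditional OR
exp(β)), p_a, and m (even, ≥ 2). The intercept is *derived*: β₀ solves

    Σ_g logistic(β₀ + β g) · Binom(g; m, p_a) = K.

The left side is strictly increasing in β₀, so the root is unique; we find it
with Brent's method, which reproduces K to better than 1e-10. The search
bracket is ±(60 + |β|·m): the root scales like −β·E[G] (for K=1%, OR=3,
m=200, p=0.25 it already sits near −70), so a fixed-width bracket would fail
on routine grid points. All pmf work is done in log space
(`binom.logpmf`, `log_expit`, log-sum-exp), which keeps m up to a few
thousand alleles stable.

The heterogeneous variant replaces βg with Σ_j β_j g_j,
g_j ~ Binomial(2, p_j) independent. Its score distribution is continuous and
not enumerable, so β₀ is calibrated by Monte Carlo: a fixed population of
10⁶ scores is drawn once, and β₀ solves mean(logistic(β₀ + score)) = K on
those same draws. Common random numbers make the objective monotone and the
result deterministic given the seed; residual error is the Monte-Carlo error
of the draw (≈ √(K(1−K)/10⁶) on the prevalence scale).

## Focal-SNP theory and the marginal odds ratio

For one SNP of interest, X ∈ {0,1,2} with X ~ Binomial(2, p_a), and the
background Z = G − X ~ Binomial(m−2, p_a) independent of X. Bayes' rule
gives, in closed form,

    P(X=x | Y=y) ∝ Binom(x; 2, p_a) · Σ_z P(Y=y | G=x+z) · Binom(z; m−2, p_a).

Single-SNP analysis fits logistic(case status ~ genotype count). Its
large-sample limit in a case-control study with case fraction φ (0.5
throughout) is the slope of the weighted logistic ML fit on the three-point
design with weights φ·P(x|Y=1) and (1−φ)·P(x|Y=0); the marginal OR is the
exponential of that slope. The weighting uses the *study* case fraction, not
the population prevalence, because the estimates being emulated come from
1:1 case-control samples (under a logistic model, case-control sampling
shifts only the intercept, but the finite design MLE is computed on the
sampled mixture for fidelity). The marginal OR is defined as this per-allele
logistic slope — the standard GWAS additive test — rather than the 2×2
allele-table OR; the allele-table estimator is available as an alternative
(`estimate_or(..., method="allele_table")`), and the two coincide under the
null.

## Simulation design

**Fixed-effects path.** Each replicate draws case genotype counts
Multinomial(n_cases, P(X|Y=1)) and control counts
Multinomial(n_controls, P(X|Y=0)) — exactly equivalent to simulating all
m/2 SNPs per subject and keeping the focal one, since the background is
marginalized analytically. Defaults mirror the study conditions: 3,500
subjects at a 1:1 case:control ratio, 10,000 replicates, median of the
per-replicate ORs reported.

**Heterogeneous path.** Each replicate rejection-samples subjects: genotypes
g_j ~ Binomial(2, p_j) (generated as the sum of two Bernoulli(p_j) draws
from uniform streams — identical in distribution, substantially faster),
score Σ β_j g_j, status Y ~ Bernoulli(logistic(β₀ + score)); the first 2,500
cases and 2,500 controls in draw order are kept. Expected cost is
n_cases/K ≈ 250,000 draws per replicate at K=1%; an iteration cap guards
against a miscalibrated intercept. The architecture (β_j, p_j) is drawn once
and held fixed across replicates.

**Estimation.** Per-replicate logistic fits reduce to two-parameter Newton
iterations on the six genotype-by-status cell counts; these are batched
across replicates (and across SNPs), which is what makes 10⁴-replicate grids
cheap. The fitter is validated against statsmodels GLM and a dense
grid-search ML oracle in the tests. Tables with separation or zero cells
(common at low MAF) fall back to the Haldane-Anscombe-corrected (+0.5)
allele-table OR and are counted in `n_fallback`; dropping them would bias
the median. Medians over an even number of replicates use the standard
midpoint convention.

**Reproducibility.** Every experiment is a pure function of its parameters
and a master seed. The fixed-effects path consumes one seeded generator;
the heterogeneous path gives replicate r the r-th child of
`SeedSequence(master_seed)`, so results are independent of execution order.

## Explained variance

McKelvey-Zavoina R² on the log-odds scale: R² = V / (V + π²/3), where
V = Σ_j β_j² · 2 p_j (1 − p_j) is the variance of the linear predictor under
HWE and linkage equilibrium and π²/3 is the variance of the standard
logistic error. No additional liability error variance is modeled — the
error variance is left implicit and constant. The "estimated" R² plugs the
median single-SNP log ORs into the same formula with the *true* allele
frequencies, so the reported loss isolates odds-ratio attenuation.
`solve_beta_for_r2` inverts the formula to construct scenarios with a target
heritability (e.g. the 80% flagship disease). Loss is reported both in
absolute percentage points of R² (the primary reading) and as a relative
fraction of the true R².

## Numerical and design choices

- Intercept calibration by root-finding rather than least-squares
  minimization of the prevalence error: the root is unique, bisection-type
  methods are unconditionally convergent, and the minimized squared error at
  the root is exactly 0.
- Newton fits are damped (step clipping at 5 on the log-odds scale) and
  declared divergent beyond |slope| > 15 (OR > e¹⁵), which routes
  near-separated tables to the corrected allele-table fallback.
- Binomial(2, p) via paired float32 uniform comparisons is exact to ~6e-8 in
  p — negligible against Monte-Carlo noise at any replicate count used.
- The R² loss is *not* globally monotone in p_a: near the R² ceiling
  (high heterozygosity, large β) saturation flattens and can slightly invert
  the ordering (e.g. 0.223 at p=0.25 vs 0.220 at p=0.5 for OR 2, K=1%,
  m=200), even though the OR attenuation itself is monotone in p_a. Tests
  assert the monotone part of the pattern.

## Problem sizes

Unit tests run on small models (m ≤ 8 against brute-force enumeration;
hundreds of replicates elsewhere). The headline scenarios use 1,000
replicates (explained-variance loss) and 500 rejection-sampled cohorts
(pinned top SNP, true OR 4.74); at these sizes the Monte-Carlo standard
error of a median OR is well under 1%, so scaling below the study's 10,000
replicates changes noise, not conclusions. The analysis drivers default to
1,000 replicates per grid point (200 for the full per-SNP heterogeneous
table) and accept `--replicates` for study-scale runs.

## What the generator does and does not emulate

The simulator reproduces the study conditions exactly: binomial risk-allele
counts under HWE/linkage equilibrium, logistic penetrance, 1:1 case-control
ascertainment, and (for the realistic architecture) exponential effects and
uniform frequencies. It does not model linkage disequilibrium, genotyping
error, missing data, covariates, or population stratification, and the
focal-SNP attenuation results are asymptotic statements about estimation
targets, not power calculations. Passing tests therefore demonstrate the
non-collapsibility phenomenon and its parameter dependence under the model's
assumptions — not the size of the effect in any particular real disease.

## Known limitations

- The heterogeneous intercept is Monte-Carlo calibrated; prevalence is
  matched to ≈ 1e-4 relative at the default 10⁶ draws, which is invisible in
  the OR medians but matters if one pushes K below ~10⁻⁴.
- The pinned-top-SNP scenario redraws the other 99 effects and all 100
  frequencies from their distributions; its median OR therefore varies by a
  few percent across master seeds (the architecture, not just the sampling,
  is random).
- `asymptotic_marginal_or` warns and reduces the design if a genotype class
  has numerically vanished (p_a extremely close to 0 or 1).
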