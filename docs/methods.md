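# Methods

## The model and what the tests detect

`latentgxe` targets a specific failure mode of binary-trait GWAS: a SNP
interacts with an environmental (or genetic) factor that was never
measured. The generative model is a latent-threshold regression,

    Y = 1{ Y* >= 0 },
    Y* = beta0 + betaG*G + betaE*E + betaGE*G*E + eps,

with `G` the minor-allele count (0/1/2, HWE with frequency `p`), `E ~
N(0, sigmaE^2)` independent of `G`, and `eps` a standard normal (probit)
or standard logistic (logit) error. When `E` is observed this is an
ordinary GLM with an interaction term. When `E` is latent, marginalising
it out leaves a model for `P(Y=1|G)` that is still *saturated* in the
three genotype classes: each class `g` carries a linear-predictor value

    gamma_g = (beta0 + betaG*g) / c(g),
    c(g)    = sqrt(sigma_eps^2 + (betaE + betaGE*g)^2 * sigmaE^2),

on the scale of the standardised compound error `(eps - E*)/c(g)`. The
key observation is that `c(g)` depends on `g` *only through* `betaGE`:
with no interaction the class effects are an exact arithmetic
progression and the induced dominance effect

    gammaD = gamma2 - 2*gamma1 + gamma0

is identically zero; any latent interaction generically bends the
profile and makes `gammaD != 0`. Testing the dominance coefficient is
therefore an *indirect* test for latent interaction — the binary-trait
analogue of vQTL screening for quantitative traits, which is unavailable
here because a Bernoulli variance is a function of its mean.

For probit `eps` the standardised error is again standard normal, so the
mapping above is exact; for logit it holds approximately (the
standardised logistic mixture is not exactly logistic). Since the class
model is saturated, *fitting* it with any link is free of
misspecification — only the theory-layer mapping from latent parameters
to `gamma` values carries the approximation, and `GenotypicEffects.exact`
flags it.

## Encodings and the two tests

The saturated model is reported in the Fisher-orthogonal
parameterisation `eta(G) = beta0* + betaA* G_A + betaD* G_D` with
`G_D = (-p/q, 1, -q/p)`. Under HWE this dominance column has mean 0,
variance 1, and zero covariance with `G_A`, giving a clean
additive/non-additive partition with closed forms

    betaA* = p*gammaD + (gamma1 - gamma0),
    betaD* = -p*q*gammaD,
    R2_D   = betaD*^2 / (2pq*betaA*^2 + betaD*^2).

Two Wald tests are exposed, both computed from the MLE and the observed
Fisher information:

* **non-additive (1 df)**: `H0: betaD* = 0` — the indirect interaction
  test;
* **joint (2 df)**: `H0: betaA* = betaD* = 0` — main effect and latent
  interaction together.

Both statistics are invariant to the choice of saturated dominance
encoding (orthogonal, over-dominance `(0,1,0)`, genotypic indicators);
the package verifies this numerically to ~10^-13 relative. Over-dominance
is offered for parity with PLINK2's dominance term, and the genotypic
one-hot design as the canonical saturated parameterisation.

`p` for the orthogonal encoding is the sample minor-allele frequency of
the analysed (complete-case) individuals, with automatic flipping so the
minor allele is always counted; the dominance and joint tests are
invariant to the flip.

## GLM fitting

`fit_binary_glm` is a Fisher-scoring iteration with step-halving and
analytic score/Hessian. Convergence is declared when the largest score
component falls below 1e-8 or the relative log-likelihood change falls
below 1e-10 (at most 100 iterations); one further Newton step is then
taken, which squares the residual score so that equivalent saturated
parameterisations of the same model agree to near machine precision
rather than to the stopping tolerance. The reported covariance is the
inverse *observed* information at the MLE (identical to the expected
information for the canonical logit link; computed from the analytic
second derivative for probit). The fit is validated coefficient-by-
coefficient against statsmodels GLM in the test suite.

Degenerate designs are reported, never guessed at: rank-deficient
designs return `inestimable` with the offending column named;
coefficients exceeding 15 on the link scale are reported as `separated`
(under complete separation the score vanishes while the estimates
diverge, so the magnitude bound — not the gradient — is the operative
check). A genotype class with zero cases but non-zero membership is
allowed (the MLE can remain finite); a missing genotype class makes the
dominance test `inestimable` and degrades the joint test to the 1-df
additive test with an explicit `additive_fallback` status. No Firth or
saddlepoint correction is applied — the method is defined through the
plain-MLE Wald framework, and small-sample-corrected variants would
change the object under study.

## Analytic power

Under probit truth the asymptotic power of either test is computed
without simulation: map latent parameters to `beta*`; form the expected
information `I = n * sum_g HWE(g) w(eta_g) x_g x_g'` with
`w = f^2/(F(1-F))`; compute the non-centrality
`lambda = (L beta*)' (L I^-1 L')^{-1} (L beta*)`; and evaluate
`1 - F_{chi2(d,lambda)}(chi2_d^{-1}(1-alpha))`. The default `alpha` is
the genome-wide 5e-8. The intercept is always re-solved so the
population prevalence matches its target (closed form for probit,
Gauss–Hermite quadrature for logit; residual < 1e-8).

Two structural properties of the power surface are exposed and tested:
the mirror symmetry under `(betaE, betaGE) -> (-betaE, -betaGE)`
(inherited from the sign symmetry of `gammaD`), and the existence of
*blind spots* — parameter pairs with both `betaG` and `betaGE` away from
zero whose induced `betaA*` and `betaD*` nearly cancel, leaving the
joint test with power close to `alpha`. Exact simultaneous cancellation
occurs only at the origin (verified by root-finding on
`gamma0 = gamma1 = gamma2`), so `find_blind_spot` minimises the
joint-test non-centrality along the boundary
`min(|betaG|, |betaGE|) = 0.15`; at that radius the joint-test power at
n = 30,000 (MAF 0.3, prevalence 0.1, betaE = -0.5) is below 10x the
significance level. The 0.15 radius is this package's operational
definition of "away from zero"; at radius 0.2 the minimum attainable
power is already ≈14x alpha, so the blind spot should be understood as a
near-cancellation valley that fills in as |beta| or n grows.

A known accuracy limit: the non-central chi-square formula is the
*asymptotic* power of the Wald test. At n = 30,000 the finite-sample
rejection rate of the dominance test can fall short of the formula by up
to ~1 percentage point at high power (e.g. 0.975 observed vs 0.985
analytic at betaG = -0.5, betaGE = +0.5, betaE = -0.5), an error that
vanishes as n grows. The power-bridge acceptance test compares at 3
Monte-Carlo standard errors and documents this cell as its one expected
deviation.

## Simulation studies

`simulate_dataset` draws individual-level data from the latent model.
The replication studies (type-I error, power bridge) use a fast path
that is *exactly* equivalent to fitting the GLM: with no covariates the
saturated fit reproduces the per-class case rates, the information
matrix is diagonal in the genotypic parameterisation, and the dominance
and joint Wald statistics have closed forms in the six per-class counts
(`collapsed_wald`). Per-individual latent draws are still required (the
case count within a class is a Poisson-binomial over the `E` draws), but
replications vectorise in chunks. Equality of the two paths is tested to
1e-9 relative.

The type-I study regenerates the published null design: a logistic model
with `beta0 = -1`, `betaGE = 0`, `E ~ N(0,1)`, `betaG = 0.5` for the
dominance test and `betaG = 0` for the joint test, over MAF in {0.1,
0.3, 0.5} x betaE in {0, 1} (no covariates; trait prevalence emerges at
roughly 0.3–0.4). The reference study used B = 100,000 replications of
n = 100,000; the package's default desk scale is B = 2,000 of
n = 20,000, with B up to 50,000 used for the rarest tail (alpha =
0.0005) in the acceptance script. At n = 20,000 the extreme tail of the
dominance test runs very slightly conservative (empirical ~0.0004–0.0005
at alpha = 0.0005 over B = 100,000), converging to nominal at the full
sample size. Degenerate replications (a genotype class empty or without
both outcomes) are counted and reported, never dropped silently; at
these scales they do not occur.

## The synthetic cohort fixture

`make_fixture_panel` emulates a biobank-style case-control cohort: a
binary trait at prevalence ~0.12 (logistic liability with the intercept
calibrated to the realised covariate draw), covariates (age uniform
40–70 with +0.02/year, sex Bernoulli(0.5) with +0.5, four standard-normal
genotype PCs at +0.05 each on the liability), and independent HWE SNPs
with MAFs uniform in a configurable range. Planted effects are additive
(`beta*G`), dominance (`beta*1{G=1}`), or a latent G×G product
(`beta*G_c*G_idx`) whose index SNP plays the role of the unmeasured
interactor and induces a marginal dominance signal at the candidate.

What the fixture does *not* emulate: linkage disequilibrium between
panel SNPs (independent by design, except through planted products),
ascertained case-control sampling, relatedness/population structure
beyond the synthetic PCs, genotyping error, or imputation dosages.
Passing tests on this fixture therefore demonstrate calibration and
mechanics of the tests, not robustness to the cryptic structure of a
real cohort.

The induced dominance from a latent G×G product is strongly non-linear
in the product effect and index MAF (it changes sign near beta ≈ 0.9 at
index MAF 0.3); the attenuation study's fixture uses MAF in (0.4, 0.5)
and beta = 1.2, chosen from the closed-form induced-`gammaD` calculation
so the candidate's marginal dominance is ~2–2.5 standard errors at
n = 8,000.

## Scan and follow-up

`run_scan` applies per-SNP QC (MAF >= 0.01, call rate >= 0.8, HWE
goodness-of-fit p >= 1e-50 — all overridable), then runs the additive,
dominance and joint tests per SNP with user-supplied covariates, one row
per input SNP including filtered ones, so the accounting
`#input = #tested + #filtered + #failed` always holds. The scan path
contains no random numbers. Calibration is summarised by the
genomic-control lambda: observed median of the back-transformed
chi-square statistics over the null median, at the df of the matching
test. The permutation scan (`permutation_null_scan`) permutes the
phenotype once (seeded) and reruns the full scan, the standard
empirical-null check.

`interaction_followup` runs direct product-term G×G tests of candidates
against an index SNP (Bonferroni at 0.05/#candidates), and
`attenuation_analysis` contrasts each candidate's dominance signal
before and after adjusting for the index SNP's main effect and its
product with the candidate — if the dominance signal is
interaction-induced, the adjusted |betaD| shrinks toward zero.

## Numerical choices

* Intercept solver: Brent on a doubling bracket, xtol 1e-10, residual
  checked against 1e-8; logit expectations by 201-node Gauss–Hermite.
* Convergence/separation constants as above; ties in the step-halving
  accept the candidate after 30 halvings.
* GC lambda requires p-values in (0, 1]; exact zeros are a caller error.
* Scan determinism: identical inputs give byte-identical tables.
* Desk-scale study sizes (B = 2,000 x n = 20,000 for type-I; B = 2,000 x
  n = 30,000 per cell for the power bridge; 5,000 SNPs x n = 8,000 for
  the permuted-scan calibration; 20 draws for the attenuation sign test)
  were chosen so each study resolves its target quantity within the
  quoted Monte-Carlo tolerance; larger sizes are a parameter away.

## Known limitations

* Hard-call genotypes only; no dosages, phasing, multi-allelic sites or
  imputation uncertainty.
* No relatedness or mixed-model correction; the scan assumes an
  already-QC'd, approximately unrelated cohort.
* The latent-model theory assumes Gaussian `E`; other latent
  distributions change the induced `gammaD` quantitatively.
* Analytic power assumes probit truth; logit-truth values are
  approximate and flagged.
* A significant dominance signal is *compatible with* latent interaction
  but does not prove it: biological dominance of the SNP itself produces
  the same signature, which is why the interaction follow-up and
  attenuation analyses exist.
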