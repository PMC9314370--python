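# Methods

## Model and tests

The package models the conditional variance of a quantitative trait as a
quadratic function of a variant's dosage G:

    v(G) = tau1 + 2*tau2*G + tau3*G^2.

This is the variance implied by a linear model in which the SNP effect is
modulated by unobserved centred environmental (or genetic) factors: writing
the combined environmental intercept as gamma1 and the combined
interaction slope as gamma2, the trait is

    y = X*beta + betaG*G + gamma1 + gamma2*G,

and (tau1, tau2; tau2, tau3) is the covariance matrix of (gamma1, gamma2).
The residual error is merged into gamma1 because its variance and tau1 are
not separately identifiable; the individual environmental factors, their
effects, and the error variance enter only through tau1..tau3 and are never
estimated individually. Under no interaction, tau2 = tau3 = 0; a variance
QTL is a variant for which that null is rejected.

Four tests of H0: tau2 = tau3 = 0 operate on the residuals e of the OLS
mean model (covariates + additive dosage term):

1. **Quadratic Breusch–Pagan (`ols`).** OLS of e^2 on (1, 2G, G^2), so the
   coefficients estimate tau directly and without constraint. The test is
   the Gaussian likelihood ratio n*log(RSS0/RSS1) against the
   intercept-only regression, referred to chi-square with 2 df. Under
   normal errors this is asymptotically equivalent to the classical
   Breusch–Pagan score statistic.
2. **Chi-square regression (`chi2`).** e^2 = v(G)*chi2_1, i.e. exact ML of
   the zero-mean normal likelihood of e with variance v(G), over
   unconstrained tau. The likelihood coincides with that of the
   variance-component model below and with a gamma regression of e^2 with
   shape 1/2 and scale 2*v(G); `loglik_chisq_form` exposes the gamma route
   and the test suite verifies the identity to 1e-10. LRT against the
   homoscedastic ML (tau1 = mean(e^2)), chi-square 2 df.
3. **Variance-component model (`vc`).** Same likelihood with
   (tau1, tau2; tau2, tau3) constrained positive semidefinite, as implied
   by the bivariate-normal random effects. Because H0 places the parameter
   on the boundary of the PSD cone, the LRT is referred to the 0.5:0.5
   mixture of chi-square with 1 and 2 df. The mixture weights are taken as
   0.5:0.5 (the standard boundary result for this nesting), not re-derived.
4. **Linear mixed model (`lmm`).** Joint ML over fixed effects and tau:
   for fixed tau the fixed effects are the WLS solution with weights
   1/v(g_i) (profiled likelihood); tau is updated by Newton–Raphson. Same
   PSD constraint and mixture null as `vc`.

`levene` (Brown–Forsythe: one-way ANOVA on |e - group median| across
hard-called genotype groups, F with (k-1, N-k) df) is included as the
standard nonparametric comparison; groups with fewer than two members are
dropped, and fewer than two usable groups is an error rather than p = 1.

Effect size of the heteroscedasticity (and of nothing else) is reported as
the likelihood-ratio pseudo-R-squared 1 - exp(-LRT/n) (Cox–Snell/Magee
form, chosen because the tests are likelihood-ratio based); the main-effect
R^2 is the partial R^2 of the SNP after covariates,
(rss_cov - rss_full)/rss_cov, the usual per-SNP quantity in GWAS practice.

## Numerical choices

- **Newton–Raphson with step-halving.** Analytic gradient and Hessian of
  the likelihood in tau; a step is accepted only if it keeps every v(g_i)
  positive and does not decrease the log-likelihood, halving up to 20
  times; when the Hessian is not a usable ascent metric the step falls
  back to a conservatively scaled gradient. Convergence when the
  log-likelihood improves by less than 1e-8, cap of 50 iterations;
  non-convergence is reported (`converged=False`) with the best point.
- **Starting values.** The Breusch–Pagan OLS coefficients start the ML
  fits. Infeasible starts (v(g) <= 0 somewhere) are repaired by inflating
  tau1 until min v(g) >= 1e-8 * var(e).
- **PSD constraint.** The unconstrained optimum is computed first; if it is
  PSD the constraint is inactive and the fit is returned as-is. Otherwise
  the constrained optimum lies on the boundary of the cone, where the
  covariance matrix is rank one: tau = (a^2, a*b, b^2) and
  v(g) = (a + b*g)^2. A two-parameter Newton ascent over (a, b) is run
  from two starts (the null point and the projection of the unconstrained
  optimum); the better optimum is kept. This is the Cholesky
  parameterization with the zero second diagonal made explicit — Newton on
  the full Cholesky factor is singular exactly at the boundary where the
  null lives. Boundary solutions are reported as converged.
- **Profiled LMM.** The tau-gradient of the profiled likelihood equals the
  fixed-residual gradient (envelope theorem); the Hessian uses the
  fixed-residual expression, which is a Gauss–Newton-style approximation —
  adequate because every candidate step re-solves the WLS fixed effects
  and is accepted only on likelihood ascent.
- **Degenerate input.** An (almost) exact mean-model fit (zero residual
  variance) raises an explicit error in every variance test instead of
  silently returning tau = 0. Fewer than three distinct genotype values
  make G and G^2 collinear and raise an error; the scan driver logs and
  skips such variants. LRTs that come out slightly negative numerically
  are clamped at zero. p-values are floored at the smallest positive
  double.
- **Hard calls.** Probability triples are called by argmax with ties
  toward the smaller genotype; dosages round to the nearest integer with
  half-integers also rounding down. Deterministic by construction.

## Trait preparation and filters

SBP and DBP are means over available measurements, with +15 and +10 mm Hg
added for samples on antihypertensive medication (the standard adjustment
for treated blood pressure). Pulse pressure is the difference of the
*adjusted* SBP and DBP — adjustment first, so a medicated sample's PP
shifts by +5 mm Hg — then natural-log transformed (PP is right-skewed; the
base is a free choice and natural log keeps likelihoods simple). Variant
filters keep MAF strictly above 0.01 and info score strictly above 0.9;
sample filters drop missing trait/covariate rows and samples whose trait
or BMI lies 5 or more sample SDs from the mean, with mean and SD computed
once on the missingness-complete samples (no iterative re-screening).
Genotype missingness is handled complete-case per variant; the per-variant
n and the coded-allele frequency in the analysis sample are reported in
each scan record.

The main-effect p-value uses the normal reference for n >= 5000 and the
t(n-p) reference below (both identical in practice at biobank n).

## The synthetic cohort

`simulate` generates the study conditions the tests are validated under:

- genotypes: hard calls with allele counts Binomial(2, maf) (HWE, no LD);
- covariates: sex ~ Bernoulli(0.46), age ~ Uniform(40, 69) (the cohort age
  range of the large biobanks these methods target), BMI ~ N(27, 4.8^2)
  truncated positive, 10 standard-normal PCs;
- trait: SBP = 86.5 + 5.65*sex + 0.00827*age^2 + 0.909*BMI + 0.0647*PC4
  + 0.0349*PC9 + sum of 54 background SNP effects + eps,
  eps ~ N(0, 18.44^2) — intercept, coefficients and error SD are the
  fitted values of a biobank SBP null model. The published identities and
  effects of the 54 background SNPs are not reproduced here: the default
  background panel draws maf ~ U(0.05, 0.5) and beta ~ N(0, 0.3) mm Hg
  once per seed, for structural realism only.
- focal SNP (power studies): per-individual effect b_j ~ N(-0.475,
  sigma^2) i.i.d. across individuals. The i.i.d.-per-individual draw is
  what maps the effect variance onto the variance law (tau3 = sigma^2,
  tau2 = 0, since b is independent of eps); a per-replicate constant
  effect would induce no within-replicate heteroscedasticity and could
  not be the intended design. The generator always draws the standardized
  slopes and scales them by sigma, so sigma^2 = 0 reproduces the
  constant-effect null exactly under the same seed, and the same
  replicate noise is reused at every sigma^2 level (common random
  numbers), which makes power comparisons across levels and across tests
  sharp even when the effects are small.

What the generator does **not** emulate: linkage disequilibrium, dosage
uncertainty (it emits hard calls), population structure behind the PCs,
relatedness, and non-Gaussian trait errors. Passing calibration and power
checks on these cohorts therefore demonstrates correctness of the
estimators and reference distributions under the model's assumptions, not
robustness to the full messiness of real biobank data.

Seeding is hierarchical: a master seed plus fixed integer tags feed
`numpy.random.SeedSequence`, so every stream (covariates, background
genotypes, test SNPs, replicate r's noise) is reproducible in isolation
and whole studies are bit-reproducible.

## Problem sizes and test design

The validation studies run at desk scale, chosen so the whole suite
completes in minutes while keeping each check statistically sharp:
null calibration at n = 2000 samples x 2000 null SNPs (binomial SE of the
rejection rate at alpha = 0.05 is ~0.005); power at n = 10,000 with 300
replicates over sigma^2 in {0.5, 1, 2}; parameter recovery at n = 50,000
with 100 replicates. Two design notes:

- Null-SNP tests that share a single simulated trait are positively
  correlated through that trait's realized residual kurtosis, so at desk
  scale the calibration batches its SNPs over a few independently drawn
  traits (`n_traits` in `null_calibration`), restoring the independence a
  binomial error band assumes. At biobank n the shared fluctuation is
  negligible and one trait suffices.
- Parameter recovery and the lmm/vc agreement check use the minimal
  random-slope generator at unit error scale (tau1 = 1): per-replicate
  sampling noise of tau3-hat scales with tau1, and at the SBP error scale
  (tau1 ~ 340 mm Hg^2) the Monte-Carlo error of a 100-replicate mean
  would swamp a 10% recovery tolerance at any implementable n. The
  estimator is identical in both settings; only the noise scale differs.

The biobank-scale configuration (n = 396,387, 1000 replicates, alpha =
5e-8) is available as `SimulationSpec.biobank_scale()` for users with the
compute to run it.

## Known limitations

- The mixture null uses fixed 0.5:0.5 weights; with estimated nuisance
  parameters the exact cone weights can deviate slightly, which is
  invisible at these sample sizes but untested at n < ~500.
- The scan is single-threaded (the `threads` field is accepted for
  interface stability; variants are independent work units and results
  are emitted in input order, so parallel execution is a safe future
  extension).
- No REML variants, no sandwich/robust variance tests, no mean-dispersion
  joint modelling beyond the quadratic variance law, no meta-analysis of
  tau estimates across cohorts.
- BGEN/PLINK-bed input, LD clumping of significant variants into loci,
  and annotation lookups are out of scope; QQ coordinates are computed
  but plot rendering is left to the user.
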