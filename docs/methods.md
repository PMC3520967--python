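# Methods

## The model

`multinmix` fits a hierarchical N-mixture abundance model to repeated counts
of unmarked individuals collected with **two independent detection methods**
(the motivating case: grizzly-bear hair traps, a systematic method with 4
sampling occasions, and bear rubs, an opportunistic method with 5 occasions).

Latent local abundance at site *i* is Poisson,

    N_i ~ Poisson(lambda_i),      log lambda_i = beta0 + sum_j w_j beta_j x_ij,

and each observed count is binomial conditional on abundance, with a separate
logit-linear detection component per method *m*:

    y_itm ~ Binomial(N_i, p_itm),  logit p_itm = alpha0_m + sum_k alpha_mk v_itmk.

Site/occasion cells without sampling effort are masked and contribute nothing
to the likelihood. Abundance covariates are site-level; detection covariates
are site-level but may vary by occasion.

Model selection uses Kuo–Mallick binary inclusion indicators `w_j ~
Bernoulli(pi_j)` on the abundance covariates. A covariate's *weight* is the
fraction of posterior samples with `w_j = 1`; a covariate is *important* when
its weight is at least 0.5 (inclusive — the median-probability-model rule). A
*model* is a distinct included set, its weight the fraction of samples
showing exactly that set; "best models" are reported up to cumulative weight
0.5.

Assumptions worth stating explicitly: sites are independent (no spatial
autocorrelation), the population is closed over the sampling season,
detections are independent between methods and across occasions, and both
methods count distinct individuals without misidentification.

## Priors

The counts alone say nothing about priors, so the defaults are proper but
vague on *standardized* covariates: Normal(0, 3.16) on every regression
coefficient (variance 10), and prior inclusion probability 0.5 per indicator,
which makes model weights interpretable as posterior model probabilities
under a uniform prior over models. Covariates are standardized (center/scale
stored for prediction) before fitting; this also keeps a single coefficient
prior sensible and stabilizes the random-walk proposals.

## Sampler

Inference is Metropolis-within-Gibbs, one JIT-compiled kernel per chain:

1. **Latent abundance.** Per site, a symmetric integer random walk
   `N' = N ± U{1..5}` (rejected outright below the support bound
   `N >= max observed count`), followed by a Metropolized independence
   proposal `N' ~ Poisson(lambda_i)`. For the independence move the Poisson
   factors cancel, leaving a binomial-only acceptance ratio; it lets the
   chain cross the funnel between `lambda` and `N` that a +/-5 walk cannot,
   which matters both for vague-prior regimes and for the prior-recovery
   property (with fully masked data every marginal must equal its prior).
2. **Coefficients.** Scalar Gaussian random-walk MH for the abundance
   intercept and each *included* slope; slopes whose indicator is 0 are
   redrawn from their prior (the standard Kuo–Mallick move, which keeps the
   excluded-slope proposal distribution healthy). Each method's detection
   block (intercept + slopes) is updated jointly with a Gaussian random-walk.
3. **Indicators.** Exact Bernoulli full conditional per covariate holding its
   slope fixed; only the Poisson terms enter, because conditioning on `N`
   separates the abundance and detection halves of the likelihood.

Proposal scales adapt by factors of 1.3 toward a 25–45% acceptance window
during burn-in only (windows of 100 iterations) and are frozen afterwards, so
the post-burn-in chain is a fixed Markov kernel. Chains start overdispersed:
coefficients from Normal(0, 2 x proposal scale), latent `N` at
max observed count + 1, all indicators at 1.

The default run protocol is 3 chains, burn-in 10,000, keeping every 20th of
190,000 iterations — 9,000 saved draws per chain. All randomness flows from
one master seed through per-chain substreams; identical configurations give
bitwise-identical posterior files.

## Convergence

`bgr_statistic` is the interval-based Brooks–Gelman–Rubin potential scale
reduction factor: the width of the pooled empirical 80% interval divided by
the mean within-chain 80% interval width, using inverted-CDF quantiles (so
exact chain copies give exactly 1.0). The working rule is max BGR <= 1.01
over all monitored continuous parameters; fits exceeding it are flagged in
the convergence report and a warning is logged. The interval form (rather
than the variance-ratio PSRF) matches the diagnostic popularized by the BUGS
family of samplers and behaves sensibly for the mixture-shaped marginals
that indicator selection produces.

## The three-analysis comparison

`fit_three_analyses` reproduces the single-vs-joint workflow: the selection
model is fitted to (1) method 1 alone, (2) method 2 alone, (3) both methods,
where "alone" means the other method's occasions are masked — all three fits
share one parameterization and RNG path, so masking a method entirely *is*
the single-method analysis. Only sites with effort in both methods are
analyzed (sites lacking either are dropped with a warning). Each analysis is
then refitted with only its important covariates (indicators fixed at 1),
and local abundance is summarized as the per-site posterior **lower median**
of the latent `N` draws — integer-valued and reproducible without
interpolation. Relative abundance divides by the maximum median for that
analysis, mapping each analysis onto [0, 1].

`classify_change` compares the three relative surfaces per site:
`d1 = combined − method1-only` (the impact of adding method 2) and
`d2 = combined − method2-only`. Sites where the two impacts have strictly
opposite signs are the disagreement map; both impacts within 1e-6 of zero is
"no change"; anything else is concordant.

## Synthetic scenarios

No field dataset ships with the package, so the generator reproduces the
statistical structure the analysis assumes:

- 245 sites by default (the dually-sampled female-scale grid), occasions
  (4, 5), 15 candidate abundance covariates drawn multivariate normal with
  exchangeable pairwise correlation 0.3 (landscape covariates are never
  orthogonal), then standardized.
- Detection covariates per method: an occasion-driven "Julian day" analogue
  and a right-skewed site-level effort covariate, standardized; detection
  intercepts are solved numerically so the median per-occasion detection
  probability hits its target — defaults 0.07 (hair trap) and 0.13 (bear
  rub), the low-detection regime reported for this kind of survey.
- Mean abundance exp(beta0) = 3 bears per cell, a realistic density for a
  recovering grizzly population at this grid scale.
- Optionally a fraction of sites (default 0.31, as in the motivating survey
  where 198 of 641 cells had no bear-rub effort) loses all method-2 effort.
- **Heterogeneity**: the population splits into two latent subgroups with
  their own abundance coefficients and a per-subgroup x per-method
  susceptibility multiplier on detection, implemented at the subgroup level
  as thinned Poisson components, so "a segment invisible to one method" is
  expressible exactly (susceptibility 0). The effort mask is assigned by a
  seeded uniform draw per site, not spatially blocked: the missing cells in
  the motivating survey were budget-driven, and spatial structure is out of
  scope.

Two frozen presets drive the tests:

- `shared_population`: homogeneous, both methods sample everyone, 2 of 15
  covariates truly active (standardized effects +0.75 and −0.75), every site
  sampled by both methods (matching an analysis restricted to dually sampled
  cells). Under this preset single-method and combined analyses should agree.
- `heterogeneous_subpopulations`: half the expected abundance sits in a
  subgroup invisible to method 1 and responding to a different covariate
  (effect +0.75 on covariate 2 instead of covariate 1). Method 1 then sees
  only the covariate-1 signal while method 2 sees a mixture — the mechanism
  by which two methods select different "important" variables.

What the generator does **not** emulate: spatial autocorrelation between
cells, between-method detection correlation (individuals attracted or averse
to both methods at once), open-population turnover, misidentification, and
covariate measurement error. Passing recovery tests therefore show the
machinery is correct *under the model's own assumptions*, not that the model
is robust to their violation.

## Numerical choices

- Impossible states (`y > N`) propagate a −1e300 sentinel rather than NaN in
  accept/reject arithmetic.
- `marginal_site_loglik` truncates the latent sum at K and refuses to answer
  if the Poisson tail above K carries mass >= 1e-8; it is the exact-inference
  oracle used to validate the sampler.
- Binomial coefficients inside the kernel come from a precomputed
  log-gamma table (latent abundance above ~100,000 is rejected outright —
  far beyond the generator's overflow guard at lambda = 1e6).
- Lower (integer) medians for abundance summaries; inverted-CDF quantiles in
  the BGR statistic; ties in model-weight tables break lexicographically.
- Relative abundance of an all-zero analysis is defined as all zeros.

## Problem sizes used in the test suite

Statistical acceptance checks run at the scale the scenarios define: the
toy-oracle comparison uses 3 sites with dense-grid integration (two-pass
adaptive grids, 41 points per axis); replicate studies use 20 shared-preset
and 11 heterogeneous-preset replicates at 245 sites with single chains of
20,000 iterations; the convergence check runs the full default protocol
(3 x 190,000). Unit tests use 8–60 site scenarios. These sizes were chosen
so the whole suite completes on one CPU in well under half an hour while
keeping every Monte-Carlo tolerance honest (3 Monte-Carlo standard errors
wherever an exact oracle exists).

## Known limitations

- Single abundance stratum: no sex/age-specific submodels; run separate
  analyses per stratum as the motivating study did.
- The negative-binomial abundance variant is not implemented.
- Indicator selection is over abundance covariates only; detection
  covariates are always included.
- The Kuo–Mallick step can mix slowly when candidate covariates are very
  highly correlated (|r| > ~0.9); the duplicate-covariate exchangeability
  test bounds the symptom but strong collinearity still deserves longer
  chains and a look at the per-parameter BGR values.
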