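# multinmix

Hierarchical N-mixture abundance models for repeated count surveys that use
**more than one detection method**, with Bayesian variable selection and a
single-method vs. joint-method comparison workflow.

## The problem

Wildlife surveys often deploy several detection methods at once — for
example, baited hair traps (systematic) and naturally used bear rubs
(opportunistic) for grizzly bears. Combining methods increases sample size
and precision, but if individuals differ in their susceptibility to the
methods, each method effectively samples a different segment of the
population. When the goal is identifying which *landscape variables drive
local abundance*, pooling such methods can silently average away a
subpopulation's signal. `multinmix` is for ecologists and biostatisticians
who want to fit the joint model *and* check whether it is telling the same
story as each method alone.

## The model

Counts of distinct individuals `y[i, t, m]` at site *i*, occasion *t*,
method *m* follow an N-mixture model with one detection component per
method:

    N_i     ~ Poisson(lambda_i)            log lambda_i = beta0 + sum_j w_j beta_j x_ij
    y_itm   ~ Binomial(N_i, p_itm)         logit p_itm  = alpha0_m + sum_k alpha_mk v_itmk
    w_j     ~ Bernoulli(0.5)               (Kuo-Mallick inclusion indicators)

Inference is Metropolis-within-Gibbs (JIT-compiled; default protocol 3
chains, burn-in 10,000, every 20th of 190,000 iterations) with the
Brooks–Gelman–Rubin statistic (BGR ≤ 1.01) as the convergence rule. A
covariate is *important* when its indicator is on in ≥ 50% of posterior
samples; model weights are the posterior frequencies of the distinct
included sets. Sites or occasions without sampling effort are masked out of
the likelihood, so methods with unequal effort coverage are handled
natively. See `docs/methods.md` for the full account.

## Worked example

Simulate a two-method survey from the built-in shared-population scenario
(245 cells, 2 of 15 candidate covariates truly active with standardized
effects +0.75 and −0.75, median per-occasion detection 0.07 / 0.13), fit the
combined model, and look at the selection output:

```python
from dataclasses import replace
import multinmix.synthetic_data as sd
import multinmix.sampler as sp
import multinmix.selection as sel

dataset = sd.make_dataset(replace(sd.get_preset("shared_population"), seed=5))
fit = sp.run_mcmc(dataset.counts, dataset.abund_design, dataset.det_design,
                  sp.SamplerConfig(seed=1))

print("max BGR:", round(float(fit.rhat().max()), 4))
print(sel.variable_weights(fit).round(3).head(4))
print(sel.model_weights(fit).top_models(0.5))
```

prints (about two minutes on one CPU):

```
max BGR: 1.0012
x1    1.000
x2    1.000
x3    0.016
x4    0.015
Name: weight, dtype: float64
      model  count    weight  cumulative
0  (x1, x2)  20566  0.761704    0.761704
```

The two truly active covariates get weight 1.000, every spurious one stays
near the 0.02 noise floor, and the single best model — exactly the true
covariate set — already carries 76% of the posterior model weight. The
three-analysis comparison (`multinmix.prediction_compare.fit_three_analyses`
or the `compare` CLI subcommand) repeats this for method-1-only,
method-2-only and combined data, refits each with only its important
variables, and classifies the grid cells where adding the second method
moved relative predicted abundance in opposite directions.

A command-line interface wraps the same workflow for file-based runs
(`multinmix simulate|fit|select|predict|compare|all --config config.yaml`);
every output file carries the configuration hash and master seed, and
identical configurations reproduce byte-identical outputs.

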