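# ctxddm

Hierarchical Bayesian models of how a real-world context — a gambling venue
versus a neutral café — shifts two computational markers studied in
behavioural addiction: **temporal discounting** and **model-based versus
model-free reinforcement learning**.  The package is aimed at computational
psychiatry researchers who want to simulate, fit and criticize these models
end-to-end on synthetic cohorts or on their own trial-level choice/RT data.

## Models

**Intertemporal choice.**  Subjective value of the larger-later option
follows single-parameter hyperbolic discounting with the rate in log-space
and an additive context shift (`I_t` = 1 in the gambling context):

    SV(LL_t) = A_t / (1 + exp(k + s_k I_t) D_t),      SV(SS) = 20 EUR

Choice rules: a softmax in `(beta + s_beta I)(SV(LL) - 20)`, or Wiener
first-passage (drift-diffusion) likelihoods of the signed response time
(LL = upper boundary) with a value-free drift (`ddm0`), a drift linear in
the value difference (`ddm_lin`, `v_t = v_coeff (SV(LL) - 20)`), or that
input squashed through an odd sigmoid with asymptote `v_max` (`ddm_s`).

**Two-step task.**  A hybrid learner updates model-free Q-values at both
stages by prediction errors (separate learning rates, eligibility trace 1),
recomputes model-based stage-1 values by a Bellman lookahead over the 70/30
transition structure, decays all unchosen values toward the reward-walk
mean, and chooses by softmax (`beta_MB`, `beta_MF`, `beta_2`, perseveration
`rho`) or by per-stage drift-diffusion rules whose drifts weight the MB/MF
value differences (`rlddm_lin`, `rlddm_s`, plus a value-free `rlddm_null`).

Every parameter `x` carries a context shift `s_x`; each baseline and each
shift gets its own group-level distribution.  Fits are compared by WAIC and
context effects summarized by directional Bayes factors (posterior mass
above vs. below zero) and posterior predictive checks.

## Worked example

Simulate a 12-subject cohort from the softmax discounting model at the
package's default group parameters (discount-rate shift `s_k = 0.77`), fit
it hierarchically, and summarize the context effect:

```python
from ctxddm import synthetic, inference

design = synthetic.make_discounting_design(version=1, context_order=(0, 1), seed=3)
cohort = synthetic.default_cohort_spec("softmax", n_subjects=12, seed=7)
data = synthetic.simulate_discounting_cohort(cohort, design, "softmax")

mcmc = inference.MCMCSettings(chains=2, burn_in=600, draws=800, thin=2)
fit = inference.fit_hierarchical("softmax", data, mcmc=mcmc, seed=11)

summary = fit.summary().set_index("parameter").round(3)
print(summary[["mean", "sd", "hdi95_low", "hdi95_high", "directional_bf"]])
bf = inference.directional_bf(fit.group_mean_draws("s_k_log"))
print(f"\ns_k dBF = {bf.value:.1f} ({bf.band}, {bf.direction})")
```

Output:

```
            mean     sd  hdi95_low  hdi95_high  directional_bf
parameter
k_log     -4.306  0.330     -4.902      -3.587             NaN
beta       0.236  0.031      0.183       0.303             NaN
s_k_log    0.581  0.102      0.391       0.773             inf
s_beta     0.051  0.025      0.007       0.106          40.298

s_k dBF = inf (extreme, positive)
```

Reading: the group-mean discount rate log(k) is about −4.3 in the neutral
context, and the shift posterior `s_k_log` sits well above zero (95% HDI
[0.39, 0.77]) — the fit recovers the simulated steepening of discounting in
the gambling context (true shift 0.77, true baseline −4.0, with the usual
hierarchical shrinkage at 12 subjects).  Every retained draw of `s_k_log`
is positive, so the directional Bayes factor is reported as infinite and
flagged as capped; `s_beta` is small, matching the small simulated shift in
choice stochasticity.

The same surface drives the other models, e.g.
`fit_hierarchical("ddm_s", preprocess_discounting_rts(df), ...)` for the
sigmoid-drift DDM, `compare_models([...])` for WAIC rankings,
`diagnostics.ppc_discounting(fit, df)` for RT-by-conflict posterior
predictive checks, and `diagnostics.stay_probability_analysis(df)` for the
two-step stay-probability signatures.  A `ctxddm` command-line interface
wraps the pipeline (`simulate`, `fit`, `compare`, `ppc`, `recover`, `run`).

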