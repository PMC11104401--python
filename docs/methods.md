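# Methods

`ctxddm` models how a real-world context — a gambling venue versus a neutral
café — shifts the latent parameters of two decision tasks performed by the
same participants: an intertemporal-choice task and a two-step sequential
reinforcement-learning task.  This note documents the models, the synthetic
cohorts the package tests itself on, the inference machinery, and the
numerical and design choices a maintainer should know about.

## Temporal discounting

Each trial offers a fixed smaller-sooner reward (SS, 20 EUR immediately)
against a larger-later reward (LL, amount `A_t` after `D_t` days).  Value
follows single-parameter hyperbolic discounting with the rate in log-space
and an additive context shift:

    SV(LL_t) = A_t / (1 + exp(k + s_k * I_t) * D_t),      SV(SS) = 20,

where `I_t` is 1 in the gambling context and 0 otherwise.  Choice rules:

- **softmax** — `P(LL) = logistic((beta + s_beta I) * (SV(LL) - 20))`.
  Money stays on its natural euro scale; SS is fixed at 20.
- **ddm0 / ddm_lin / ddm_s** — the Wiener first-passage-time likelihood of
  the signed response time (LL = upper boundary, SS = lower; SS RTs are
  negated).  `ddm0` has a value-free drift `v + s_v I`; `ddm_lin` sets the
  trial drift to `(v_coeff + s I) * (SV(LL) - 20)`; `ddm_s` additionally
  squashes that input through the odd sigmoid `S(m) = 2V/(1+exp(-m)) - V`
  with asymptote `V = v_max + s I`, letting RTs saturate for easy decisions.
  Boundary separation `alpha`, non-decision time `tau` and relative start
  `z` (on (0,1), shifts entering additively with a validity check) all carry
  their own shifts.

RT preprocessing: SS-choice RTs are multiplied by −1; per participant the
fastest and slowest `floor(0.025 n)` trials by absolute RT are removed
(floor rounding, ties broken by trial order), retaining ≈95% of trials.

## Two-step task

Stage-1 (S1) actions lead to one of two stage-2 (S2) states with fixed 70/30
transition probabilities; each S2 action pays a fluctuating reward magnitude
(Gaussian random walk, SD 2.5 points, reflecting at 0 and 100), rescaled to
[0, 1] before learning so the walk mean (50 points) matches the decay target
0.5.  The learner is a hybrid of model-free (MF) and model-based (MB) control:

- S2 MF values update by reward prediction errors with rate `eta2 + s I`.
- S1 MF values update by `eta1 * delta_1 + eta2 * delta_2`, where `delta_1`
  uses the *pre-update* S2 value of the visited state's chosen action (the
  standard hybrid convention; the update-timing alternative is noted below)
  and the S2 prediction error is passed back with an eligibility trace fixed
  at 1.
- MB values are recomputed every trial by a one-step Bellman lookahead over
  the transition structure (MB applies to S1 only).
- All unchosen Q-values at every stage decay toward 0.5:
  `Q <- Q * eta_decay + (1 - eta_decay) * 0.5` (rate 1 = no decay).
- Update order within a trial: S2 update, S1 update, decay of unchosen
  values.

Choice rules: a softmax over `beta_MB Q_MB + beta_MF Q_MF + rho rep(a)` at
S1 (perseveration `rho` rewards repeating the previous S1 action) and over
`beta_2 Q_S2` at S2; or a per-stage drift-diffusion rule (RLDDM) with z
fixed at 0.5, stage-specific `alpha` and `tau`, S1 drift
`vcoeff_MB dQ_MB + vcoeff_MF dQ_MF + rho rep`, S2 drift `vcoeff_S2 dQ_S2`,
each optionally squashed by a stage-specific sigmoid with asymptote
`vmax_Si` (`rlddm_s`).  The upper boundary is stimulus 1 of a fixed
canonical stimulus ordering.  A value-free `rlddm_null` completes the
family.  RT exclusions (per stage: 2.5% tails plus a 150 ms floor) are
implemented as likelihood masks — excluded trials still drive learning,
because the learner is sequential; only their Wiener density term is
dropped.

A caveat worth knowing: with separate learning rates the S1 update
`Q1 + eta1 (Q2 - Q1) + eta2 (r - Q2)` is a convex combination only when
`eta1 >= eta2`; when `eta2 > eta1`, S1 values can transiently leave [0, 1].
This is a property of the update equations themselves, not of the
implementation; the boundedness property test therefore conditions on
`eta1 >= eta2`.

## Synthetic cohorts (the study conditions)

The generator reproduces the task designs: LL amounts as the two printed
16-multiplier sets times 20 EUR, delays `{1,7,13,31,58,122}` and
`{2,6,15,29,62,118}` days, two counterbalanced versions alternating across
the two context sessions; 70/30 transitions; four reward walks per session
with the second session using the first session's walks reversed.  The
printed multiplier-by-delay cross has 96 cells while the task ran 140 trials
per session; the generator defaults to the 96-cell cross and reaches any
requested trial count by uniform resampling of cells (logged), since the
extra cells are not recoverable from the printed sets.

Subjects are drawn from truncated-Gaussian group distributions.  Group-mean
defaults use the study's reported posterior means where printed (for
example a softmax discount-rate shift of 0.77, a DDM discount-rate shift of
0.40, a maximum-drift-rate shift of 0.33, an S2 learning-rate shift of 0.40,
MF/MB weight shifts of −1.14/+1.08) and field-plausible values elsewhere
(baseline group means and SDs are not printed); all defaults live in
`synthetic.DEFAULT_GROUP_MEANS/SDS` and are fixed rather than tuned.  What
the generator does **not** emulate: attention lapses, session-order or
fatigue effects, contaminant RTs beyond the DDM itself, and individual
differences in transition-structure knowledge.  Passing recovery tests on
these cohorts therefore demonstrates correctness of the estimation
machinery under the model, not robustness to real-data misspecification.

## Wiener first-passage primitives

The density uses the small-time/large-time series pair with an automatic
switch to whichever series needs fewer terms at an absolute truncation
tolerance of 1e-9 on the normalized density.  Sampling is Euler–Maruyama
with step 1e-4 s plus a boundary continuity correction (boundaries pulled
inward by `0.5826 sqrt(dt)`), which removes the leading-order bias of
discrete-time crossing detection; with the correction the sampled signed-RT
distribution matches the series density to a KS distance well below 0.01 at
10^6 draws.  Samples are regenerated (never truncated) in the rare event a
walk exceeds the 30 s horizon.

## Hierarchical inference

Each baseline parameter and each shift parameter has its own group-level
Gaussian; subject values are sampled on the natural scale (shifts are
additive there) with support enforced by proposal rejection at the declared
bounds.  Priors: uniform over plausible ranges for baseline group means
(`k_log` on [−8, 1], rates on [0, 1], betas on [0, 20], `alpha` on
[0.05, 5], `tau` on [0.05, 2], declared in `default_priors.yaml` and the
registry as package defaults), zero-centered Gaussians for shift group
means, and half-Cauchy(0, 2.5) priors on group SDs.  The truncation mass of
the bounded subject-level normals is not renormalized in the group updates —
the usual convention in this literature — which can bias group SDs slightly
upward near a bound.

The sampler is adaptive Metropolis-within-Gibbs: single-site random-walk
proposals for every group mean, group SD (log-scale walk with Jacobian),
and subject-level parameter, with scales tuned toward 0.44 acceptance
during burn-in (Robbins–Monro batches) and frozen afterwards.  Likelihood
kernels are numba-compiled; a proposal for one subject re-evaluates only
that subject's likelihood.  Chains whose starting point has zero likelihood
(for instance a non-decision time above the subject's fastest RT) resample
their start uniformly until the likelihood is finite.  Convergence is gated
on rank-normalized split-chain R-hat at 1.02 over all group-level and
subject-level parameters; a failed gate triggers one sampling extension and
otherwise flags the fit (`converged=False`) rather than failing hard,
matching the reported tolerance of a single non-converging participant.
Paper-scale defaults are 2 chains, burn-in 1000, 2000 retained draws at
thinning 2; tests and desk-scale runs use smaller, explicitly stated
settings.  The hierarchical funnel mixes slowly under single-site proposals,
so desk-scale fits routinely carry the non-convergence flag; recovery
quality is what the tests assert.

WAIC is computed from pointwise posterior log-likelihoods as
`-2 (lppd - p_waic)` with `p_waic` the summed pointwise variance (ddof 1);
comparisons require identical data fingerprints.  Directional Bayes factors
are the ratio of posterior mass above zero to below zero of a shift's
group-mean posterior, from a Gaussian KDE evaluated on a grid spanning the
draws ±3 bandwidths; bands: 1–3 anecdotal, >3 moderate, >10 strong, >30
very strong, >100 extreme, reciprocals for the opposite direction.  The
covariate extension makes the subject-level mean of one shift parameter
(default the discount-rate shift) a linear function of standardized
per-subject scores, with unit-normal priors on slopes.

One comparability note: WAICs of softmax (choice-only) and DDM (choice+RT)
variants are not comparable — they are likelihoods over different
observables — so model-recovery checks run within the DDM family for each
task.

## Posterior predictive checks and model-agnostic analyses

Discounting: trials are binned per subject and context into five
equal-count bins of decision conflict `|SV(LL) - 20|`, computed from the
subject's median posterior log discount rate (quantile edges; the paper
does not state the edge rule, equal-width is the logged alternative), and
observed mean absolute RT per bin is compared with the mean over simulated
datasets drawn from random posterior draws.  Two-step: S2 RTs and the rate
of choosing the higher-reward S2 option, binned by the absolute reward
difference of the visited state's two options, observed versus re-simulated
on the same walks.  Choice accuracy scores an observed choice as predicted
when its model probability exceeds 0.5 (ties count 0.5).  The
model-agnostic analyses — choice-by-context logistic regression, S2-RT by
transition and context, and the stay-probability regression
`stay ~ previous-reward (centered) x transition (+ context)` with subject
random intercepts — are standard mixed-model fits delegated to statsmodels
(variational Bayes for the logistic random-intercept models); a reward main
effect indexes MF control, the reward-by-transition interaction MB control.

## Problem sizes used by the test suite and acceptance script

Simulation-based checks use paper-scale trial counts (140 per context for
discounting, 300 per context for the two-step task) with cohort sizes and
MCMC lengths chosen per check: 30 subjects for softmax/DDM discounting and
the softmax hybrid recovery, 10 for the RLDDM recovery, 6–8 subjects with
shortened sessions for the WAIC confusion matrices, and reduced replicate
counts for the null-shift calibration.  These sizes are the package's
desk-scale defaults; the fitting machinery itself accepts paper-scale
settings unchanged.

## Known limitations

- Single-site MH mixes slowly in the hierarchical funnel; R-hat gates are
  rarely met at desk scale (flagged, not hidden).  Blocked or gradient-based
  samplers would improve this at the cost of the dependency-free design.
- The sigmoid drift parameters (`v_coeff`, `v_max`) trade off against each
  other when drifts rarely saturate; their product is well identified, the
  factors only weakly.  The same holds for `vcoeff_mb` versus `vmax_s1` in
  the RLDDM.
- A consequence for WAIC model recovery: on data generated by a
  linear-drift model, the sigmoid variant fits with its asymptotes in their
  do-nothing (large-`vmax`) regime, where they contribute no pointwise
  likelihood variance and hence no WAIC penalty.  The two variants are then
  predictively equivalent and the WAIC margin is Monte-Carlo noise at any
  sample size, so linear-vs-sigmoid selection on linear-generated data is a
  coin toss; selection in the other direction (sigmoid-generated data, where
  saturation is expressed) is reliable.
- Group-level truncation mass is not renormalized (see above).
- The Euler sampler's accuracy depends on the step/correction pair; the KS
  check quantifies it at the default step.
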