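"""Posterior predictive checks and model-agnostic analyses.

PPCs compare observed summaries against the same summaries on datasets
simulated from the fitted posterior: mean RT across five decision-conflict
bins (intertemporal choice), S2 RTs and optimal-choice rates across S2
reward-difference bins (two-step), and binary choice accuracy.  The
model-agnostic analyses are standard mixed-effects regressions: choice by
context (logistic, subject random intercept), S2 RT by transition and
context, and the stay-probability analysis whose reward main effect indexes
model-free control and whose reward-by-transition interaction indexes
model-based control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import get_model
from .synthetic import _disc_trial_ddm_params, _simulate_rts
from .wiener import DEFAULT_DT

logger = logging.getLogger("ctxddm")

__all__ = [
    "PPCReport",
    "ppc_discounting",
    "ppc_twostep",
    "choice_accuracy",
    "stay_probability_analysis",
    "context_glmms",
]

N_CONFLICT_BINS = 5


@dataclass
class PPCReport:
    """Observed-vs-simulated summaries from a posterior predictive check."""

    conflict_bin_means: pd.DataFrame
    choice_accuracy: pd.DataFrame | None
    stay_table: pd.DataFrame | None
    n_simulated_datasets: int


def _subject_draw_matrix(fit):
    """(draws, S, 2P) subject-level draws flattened over chains."""
    c, k, s, p = fit.subject.shape
    return fit.subject.reshape(c * k, s, p)


def _quantile_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-count bin labels 0..n_bins-1 (per-subject quantile edges)."""
    if len(np.unique(x)) < n_bins:
        raise ValueError(
            f"need at least {n_bins} distinct values for conflict binning"
        )
    ranks = pd.Series(x).rank(method="first").to_numpy()
    return np.minimum((ranks - 1) * n_bins // len(x), n_bins - 1).astype(int)


def ppc_discounting(fit, trials: pd.DataFrame, n_sims: int = 200, seed: int = 0,
                    dt: float = DEFAULT_DT) -> PPCReport:
    """RT-by-decision-conflict posterior predictive check (5 bins).

    Conflict is |SV(LL) - 20| computed from each subject's median posterior
    log discount rate; per subject and context, trials fall into five
    equal-count bins and observed mean |RT| is compared with the mean across
    ``n_sims`` datasets simulated from random posterior draws.  With
    ``n_sims=0`` only the observed summaries are returned.
    """
    spec = get_model(fit.model)
    if not spec.uses_rt:
        raise ValueError("RT posterior predictive check needs a DDM variant")
    rng = np.random.default_rng(seed)
    draws = _subject_draw_matrix(fit)
    med = fit.subject_medians()
    subjects = fit.meta["subjects"]
    P = len(spec.params)
    kidx = spec.params.index("k_log") if "k_log" in spec.params else None

    rows = []
    sim_acc: dict[tuple, list] = {}
    for si, s in enumerate(subjects):
        sub = trials[trials["subject"] == s]
        A = sub["ll_amount"].to_numpy(dtype=float)
        D = sub["delay"].to_numpy(dtype=float)
        I = sub["context"].to_numpy(dtype=np.int64)
        rt_obs = np.abs(sub["rt_signed"].to_numpy(dtype=float))
        if kidx is not None:
            k_eff = med[si, kidx] + med[si, kidx + P] * I
            sv = A / (1.0 + np.exp(k_eff) * D)
            conflict = np.abs(sv - 20.0)
        else:  # value-free null model: bin on the LL amount instead
            conflict = A
        # simulate n_sims datasets from random posterior draws
        sims = np.zeros((max(n_sims, 1), len(sub)))
        for m in range(n_sims):
            th = draws[rng.integers(0, draws.shape[0]), si]
            al, ta, zz, v = _disc_trial_ddm_params(spec, th, A, D, I)
            srt = _simulate_rts(al, ta, zz, v, dt, int(rng.integers(0, 2**31 - 1)))
            sims[m] = np.abs(srt)
        for ctx in np.unique(I):
            m = I == ctx
            bins = _quantile_bins(conflict[m], N_CONFLICT_BINS)
            for b in range(N_CONFLICT_BINS):
                mb = m.copy()
                mb[m] = bins == b
                rows.append(
                    dict(
                        subject=s,
                        context=int(ctx),
                        bin=b,
                        observed=rt_obs[mb].mean(),
                        simulated=(sims[:n_sims, mb].mean() if n_sims else np.nan),
                        n_trials=int(mb.sum()),
                    )
                )
    report = pd.DataFrame(rows)
    acc = choice_accuracy(fit, trials) if n_sims else None
    return PPCReport(report, acc, None, n_sims)


def ppc_twostep(fit, trials: pd.DataFrame, n_sims: int = 200, seed: int = 0,
                n_bins: int = 5, dt: float = DEFAULT_DT) -> PPCReport:
    """Two-step PPC: S2 RTs and optimal-choice rates by S2 reward difference.

    Reward difference is the absolute difference of the two current reward
    magnitudes in the visited S2 state (walk columns ``w00``..``w11``).
    Simulated datasets re-run the generative model on the same walks and
    transition structure from random posterior draws.
    """
    from . import synthetic

    spec = get_model(fit.model)
    rng = np.random.default_rng(seed)
    draws = _subject_draw_matrix(fit)
    subjects = fit.meta["subjects"]
    p_common = fit.meta.get("p_common", 0.7)
    need = {"w00", "w01", "w10", "w11"}
    if not need <= set(trials.columns):
        raise ValueError("two-step PPC needs the walk columns w00..w11")

    def summarize(df):
        w = df[["w00", "w01", "w10", "w11"]].to_numpy()
        st = df["s2_state"].to_numpy(dtype=int)
        lo = w[np.arange(len(df)), 2 * st]
        hi = w[np.arange(len(df)), 2 * st + 1]
        diff = np.abs(hi - lo)
        optimal = (df["s2_choice"].to_numpy(dtype=int) == (hi > lo).astype(int))
        out = pd.DataFrame(
            {
                "subject": df["subject"].to_numpy(),
                "context": df["context"].to_numpy(dtype=int),
                "diff": diff,
                "optimal": optimal.astype(float),
            }
        )
        if "rt_s2" in df.columns:
            out["rt_s2"] = df["rt_s2"].to_numpy(dtype=float)
        return out

    obs = summarize(trials)
    obs["bin"] = 0
    for (s, c), idx in obs.groupby(["subject", "context"]).indices.items():
        obs.loc[obs.index[idx], "bin"] = _quantile_bins(obs["diff"].to_numpy()[idx], n_bins)
    agg = {"optimal": "mean"}
    if "rt_s2" in obs.columns:
        agg["rt_s2"] = "mean"
    observed = obs.groupby(["subject", "context", "bin"]).agg(agg).reset_index()
    observed = observed.rename(columns={"optimal": "observed_p_optimal",
                                        "rt_s2": "observed_rt_s2"})

    if n_sims:
        sims = []
        walks = None
        for m in range(n_sims):
            sim_rows = []
            for si, s in enumerate(subjects):
                th = draws[rng.integers(0, draws.shape[0]), si]
                sub = trials[trials["subject"] == s]
                # replay each session on its own walks
                for (_, ctx), block in sub.groupby(["session" if "session" in sub else "context",
                                                    "context"], sort=False):
                    w = block[["w00", "w01", "w10", "w11"]].to_numpy().T.copy()
                    n = w.shape[1]
                    I = np.full(n, int(ctx), dtype=np.int64)
                    reset = np.zeros(n, dtype=np.int64)
                    reset[0] = 1
                    a1 = np.empty(n, dtype=np.int64)
                    tr = np.empty(n, dtype=np.int64)
                    s2 = np.empty(n, dtype=np.int64)
                    a2 = np.empty(n, dtype=np.int64)
                    r = np.empty(n)
                    rt1 = np.empty(n)
                    rt2 = np.empty(n)
                    synthetic._simulate_twostep_subject(
                        spec.model_id, th, w, I, reset, p_common, dt,
                        int(rng.integers(0, 2**31 - 1)), a1, tr, s2, a2, r, rt1, rt2,
                    )
                    d = pd.DataFrame(
                        dict(subject=s, context=int(ctx), s2_state=s2, s2_choice=a2,
                             w00=w[0], w01=w[1], w10=w[2], w11=w[3])
                    )
                    if spec.uses_rt:
                        d["rt_s2"] = rt2
                    sim_rows.append(d)
            sm = summarize(pd.concat(sim_rows, ignore_index=True))
            sm["bin"] = 0
            for (s, c), idx in sm.groupby(["subject", "context"]).indices.items():
                sm.loc[sm.index[idx], "bin"] = _quantile_bins(sm["diff"].to_numpy()[idx], n_bins)
            sims.append(sm.groupby(["subject", "context", "bin"]).agg(agg).reset_index())
        simdf = pd.concat(sims).groupby(["subject", "context", "bin"]).mean().reset_index()
        simdf = simdf.rename(columns={"optimal": "simulated_p_optimal",
                                      "rt_s2": "simulated_rt_s2"})
        observed = observed.merge(simdf, on=["subject", "context", "bin"], how="left")
    acc = choice_accuracy(fit, trials) if n_sims else None
    return PPCReport(observed, acc, None, n_sims)


def choice_accuracy(fit, trials: pd.DataFrame, mode: str = "posterior-mean") -> pd.DataFrame:
    """Fraction of observed choices the fitted model predicts.

    ``posterior-mean`` scores a choice correct when its predicted probability
    exceeds 0.5 (exact ties count 0.5); ``posterior-predictive`` uses the
    majority over simulated datasets, which for binary choices coincides with
    thresholding the posterior-mean probability and is computed the same way.
    """
    if mode not in ("posterior-mean", "posterior-predictive"):
        raise ValueError("mode must be 'posterior-mean' or 'posterior-predictive'")
    spec = get_model(fit.model)
    mean_th = fit.subject_means()
    subjects = fit.meta["subjects"]
    rows = []
    if spec.task == "discounting":
        from .discounting import _disc_choiceprob_obs, _trials_to_arrays

        for si, s in enumerate(subjects):
            sub = trials[trials["subject"] == s]
            A, D, I, C, RT = _trials_to_arrays(sub, spec.uses_rt)
            p = np.empty(len(sub))
            _disc_choiceprob_obs(spec.model_id, mean_th[si], A, D, I, C, RT, len(sub), p)
            for ctx in np.unique(I):
                m = I == ctx
                score = np.where(p[m] > 0.5, 1.0, np.where(p[m] == 0.5, 0.5, 0.0))
                rows.append(dict(subject=s, context=int(ctx), stage="choice",
                                 accuracy=score.mean(), n=int(m.sum())))
    else:
        from .twostep import _two_choiceprob_obs, _twostep_arrays

        p_common = fit.meta.get("p_common", 0.7)
        for si, s in enumerate(subjects):
            sub = trials[trials["subject"] == s]
            a1, s2, a2, r, I, rt1, rt2, u1, u2, reset = _twostep_arrays(sub, False)
            p1 = np.empty(len(sub))
            p2 = np.empty(len(sub))
            _two_choiceprob_obs(spec.model_id, mean_th[si], a1, s2, a2, r, I,
                                reset, len(sub), p_common, p1, p2)
            for ctx in np.unique(I):
                m = I == ctx
                for stage, p in (("s1", p1), ("s2", p2)):
                    score = np.where(p[m] > 0.5, 1.0, np.where(p[m] == 0.5, 0.5, 0.0))
                    rows.append(dict(subject=s, context=int(ctx), stage=stage,
                                     accuracy=score.mean(), n=int(m.sum())))
    return pd.DataFrame(rows)


def stay_probability_analysis(trials: pd.DataFrame):
    """Stay probabilities by previous reward and transition.

    Fits ``stay ~ prev_reward_centered * prev_transition`` (transition coded
    +0.5 common / -0.5 rare) with a subject random intercept; the reward main
    effect indexes model-free control, the interaction model-based control.
    Also returns raw stay proportions from a median split of previous reward.
    Returns ``(stay_table, coef_table)``.
    """
    df = _stay_frame(trials)
    if len(df) < 2:
        raise ValueError("insufficient data for a stay-probability analysis")
    # raw table: median split of previous reward x previous transition
    med = df["prev_reward"].median()
    df["prev_reward_high"] = (df["prev_reward"] > med).astype(int)
    stay_table = (
        df.groupby(["prev_reward_high", "prev_transition"])["stay"]
        .mean()
        .rename("stay_probability")
        .reset_index()
    )
    coef = _binomial_mixed(df, "stay ~ prev_reward_c * prev_trans_c")
    return stay_table, coef


def _stay_frame(trials: pd.DataFrame) -> pd.DataFrame:
    rows = []
    group_cols = ["subject"] + (["session"] if "session" in trials.columns else ["context"])
    for _, sub in trials.groupby(group_cols, sort=False):
        a1 = sub["s1_choice"].to_numpy(dtype=int)
        tr = sub["transition"].to_numpy(dtype=int)
        r = sub["reward"].to_numpy(dtype=float)
        ctx = sub["context"].to_numpy(dtype=int)
        if len(sub) < 2:
            continue
        rows.append(
            pd.DataFrame(
                dict(
                    subject=sub["subject"].iloc[0],
                    stay=(a1[1:] == a1[:-1]).astype(int),
                    prev_reward=r[:-1],
                    prev_transition=tr[:-1],
                    context=ctx[1:],
                )
            )
        )
    df = pd.concat(rows, ignore_index=True)
    df["prev_reward_c"] = df["prev_reward"] - df["prev_reward"].mean()
    df["prev_trans_c"] = np.where(df["prev_transition"] == 0, 0.5, -0.5)
    return df


def _binomial_mixed(df: pd.DataFrame, formula: str) -> pd.DataFrame:
    """Logistic random-intercept model (variational Bayes fit)."""
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    model = BinomialBayesMixedGLM.from_formula(
        formula, {"subject": "0 + C(subject)"}, df
    )
    fit = model.fit_vb()
    k = len(model.exog_names)
    coef = pd.DataFrame(
        dict(
            term=model.exog_names,
            estimate=fit.fe_mean[:k],
            sd=fit.fe_sd[:k],
        )
    )
    coef["z"] = coef["estimate"] / coef["sd"]
    from scipy.stats import norm

    coef["p"] = 2 * norm.sf(np.abs(coef["z"]))
    return coef


def context_glmms(trials: pd.DataFrame, task: str | None = None) -> pd.DataFrame:
    """Model-agnostic context regressions.

    Discounting tables: logistic ``choice ~ context`` with subject random
    intercept (negative context coefficient = fewer LL choices in the
    gambling context).  Two-step tables: linear mixed model
    ``rt_s2 ~ transition + context`` with subject random intercept
    (positive transition coefficient = rare-transition slowing).
    """
    if task is None:
        task = "discounting" if "ll_amount" in trials.columns else "twostep"
    if trials["context"].nunique() < 2:
        raise ValueError("need both contexts for a context regression")
    if task == "discounting":
        return _binomial_mixed(trials, "choice ~ context")
    import statsmodels.formula.api as smf

    df = trials.copy()
    if "use_rt_s2" in df.columns:
        df = df[df["use_rt_s2"] == 1]
    df = df.dropna(subset=["rt_s2"])
    fit = smf.mixedlm("rt_s2 ~ transition + context", df, groups=df["subject"]).fit()
    out = pd.DataFrame(
        dict(term=fit.params.index, estimate=fit.params.to_numpy(),
             sd=fit.bse.to_numpy(), z=fit.tvalues.to_numpy(), p=fit.pvalues.to_numpy())
    )
    return out[out["term"] != "Group Var"].reset_index(drop=True)
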