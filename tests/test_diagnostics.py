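"""Posterior predictive checks and model-agnostic analyses."""

import numpy as np
import pandas as pd
import pytest

from conftest import cohort_with_params, make_fixed_fit
from ctxddm import synthetic
from ctxddm.diagnostics import (
    choice_accuracy,
    context_glmms,
    ppc_discounting,
    ppc_twostep,
    stay_probability_analysis,
)
from ctxddm.discounting import preprocess_discounting_rts
from ctxddm.registry import get_model, params_to_vector


def _ddm_s_cohort(n_subjects=5, seed=0):
    design = synthetic.make_discounting_design(1, (0, 1), seed=seed)
    spec = synthetic.default_cohort_spec("ddm_s", n_subjects, seed)
    df = preprocess_discounting_rts(
        synthetic.simulate_discounting_cohort(spec, design, "ddm_s")
    )
    truth = df.attrs["true_params"]
    return df, truth


class TestPPCDiscounting:
    def test_bins_partition_and_self_consistency(self):
        df, truth = _ddm_s_cohort(seed=3)
        fit = make_fixed_fit("ddm_s", df, truth)
        rep = ppc_discounting(fit, df, n_sims=40, seed=5)
        t = rep.conflict_bin_means
        # binning partitions each subject/context block
        sizes = t.groupby(["subject", "context"])["n_trials"].sum()
        blocks = df.groupby(["subject", "context"]).size()
        for key, n in blocks.items():
            assert sizes[key] == n
        # simulating from the generating parameters reproduces observed RTs
        corr = np.corrcoef(t["observed"], t["simulated"])[0, 1]
        assert corr > 0.5
        assert abs(t["observed"].mean() - t["simulated"].mean()) < 0.15

    def test_rt_decreases_as_conflict_falls(self):
        """|dSV| up -> |drift| up -> faster responses under the sigmoid DDM."""
        df, truth = _ddm_s_cohort(n_subjects=6, seed=4)
        fit = make_fixed_fit("ddm_s", df, truth)
        rep = ppc_discounting(fit, df, n_sims=0, seed=6)
        prof = rep.conflict_bin_means.groupby("bin")["observed"].mean()
        assert prof.iloc[0] > prof.iloc[-1]
        assert prof.corr(pd.Series(range(5), index=prof.index)) < 0

    def test_observed_only_mode(self):
        df, truth = _ddm_s_cohort(seed=7)
        fit = make_fixed_fit("ddm_s", df, truth)
        rep = ppc_discounting(fit, df, n_sims=0)
        assert rep.n_simulated_datasets == 0
        assert rep.conflict_bin_means["simulated"].isna().all()

    def test_degenerate_conflict_rejected(self):
        df, truth = _ddm_s_cohort(seed=8)
        df = df.assign(ll_amount=25.0, delay=31.0)  # constant dSV
        fit = make_fixed_fit("ddm_s", df, truth)
        with pytest.raises(ValueError, match="distinct"):
            ppc_discounting(fit, df, n_sims=0)


class TestPPCTwostep:
    def test_optimal_choice_rate_rises_with_reward_difference(self):
        spec = synthetic.default_cohort_spec("rlddm_s", 4, seed=9)
        df = synthetic.simulate_twostep_cohort(spec, model="rlddm_s")
        fit = make_fixed_fit("rlddm_s", df, df.attrs["true_params"])
        rep = ppc_twostep(fit, df, n_sims=10, seed=10)
        t = rep.conflict_bin_means
        prof = t.groupby("bin")["observed_p_optimal"].mean()
        assert prof.iloc[-1] > prof.iloc[0]
        assert prof.iloc[-1] > 0.6
        # simulated summaries track observed ones
        assert abs(t["simulated_p_optimal"].mean() - t["observed_p_optimal"].mean()) < 0.1

    def test_missing_walk_columns_rejected(self):
        spec = synthetic.default_cohort_spec("rlddm_s", 2, seed=11)
        df = synthetic.simulate_twostep_cohort(spec, model="rlddm_s")
        fit = make_fixed_fit("rlddm_s", df, df.attrs["true_params"])
        with pytest.raises(ValueError, match="w00"):
            ppc_twostep(fit, df.drop(columns=["w00"]), n_sims=0)


class TestChoiceAccuracy:
    def test_deterministic_agent_is_predicted_perfectly(self):
        design = synthetic.make_discounting_design(1, (0, 1), seed=12)
        gm = dict(k_log=-3.5, beta=20.0)
        spec = synthetic.CohortSpec(3, gm, {}, seed=13)
        df = synthetic.simulate_discounting_cohort(spec, design, "softmax")
        fit = make_fixed_fit("softmax", df, df.attrs["true_params"])
        acc = choice_accuracy(fit, df)
        assert acc["accuracy"].mean() > 0.97

    def test_uniform_agent_scores_half(self):
        design = synthetic.make_discounting_design(1, (0, 1), seed=14)
        spec = synthetic.CohortSpec(3, dict(k_log=-3.5, beta=0.0), {}, seed=15)
        df = synthetic.simulate_discounting_cohort(spec, design, "softmax")
        fit = make_fixed_fit("softmax", df, df.attrs["true_params"], jitter=0.0)
        acc = choice_accuracy(fit, df)
        assert acc["accuracy"].mean() == pytest.approx(0.5, abs=0.02)

    def test_twostep_accuracy_per_stage_and_context(self):
        spec = synthetic.default_cohort_spec("softmax_hybrid", 3, seed=16)
        df = synthetic.simulate_twostep_cohort(spec, model="softmax_hybrid")
        fit = make_fixed_fit("softmax_hybrid", df, df.attrs["true_params"])
        acc = choice_accuracy(fit, df)
        assert set(acc["stage"]) == {"s1", "s2"}
        assert acc["accuracy"].between(0, 1).all()
        assert acc.loc[acc.stage == "s2", "accuracy"].mean() > 0.6

    def test_invalid_mode_rejected(self):
        spec = synthetic.default_cohort_spec("softmax_hybrid", 2, seed=17)
        df = synthetic.simulate_twostep_cohort(spec, model="softmax_hybrid")
        fit = make_fixed_fit("softmax_hybrid", df, df.attrs["true_params"])
        with pytest.raises(ValueError):
            choice_accuracy(fit, df, mode="nope")


class TestStayProbabilities:
    def test_always_repeating_agent(self):
        spec = cohort_with_params("softmax_hybrid", 4, 18, beta_MB=0.0,
                                  beta_MF=0.0, beta_2=0.0, rho=5.0,
                                  s_beta_MB=0.0, s_beta_MF=0.0, s_beta_2=0.0,
                                  s_rho=0.0, s_eta1=0.0, s_eta2=0.0)
        spec.group_sds = {}
        df = synthetic.simulate_twostep_cohort(spec, model="softmax_hybrid")
        stay, _ = stay_probability_analysis(df)
        assert (stay["stay_probability"] > 0.95).all()

    def test_mb_agent_shows_reward_transition_interaction(self):
        spec = cohort_with_params("softmax_hybrid", 10, 19, beta_MB=7.0,
                                  beta_MF=0.0, rho=0.0, s_beta_MB=0.0,
                                  s_beta_MF=0.0, s_rho=0.0, s_eta1=0.0,
                                  s_eta2=0.0, s_beta_2=0.0)
        spec.group_sds = {}
        df = synthetic.simulate_twostep_cohort(spec, model="softmax_hybrid")
        _, coef = stay_probability_analysis(df)
        c = coef.set_index("term")
        inter = c.loc["prev_reward_c:prev_trans_c"]
        main = c.loc["prev_reward_c"]
        assert inter["estimate"] > 0 and inter["z"] > 2
        assert abs(main["z"]) < abs(inter["z"]) / 2

    def test_mf_agent_shows_reward_main_effect(self):
        spec = cohort_with_params("softmax_hybrid", 10, 20, beta_MB=0.0,
                                  beta_MF=7.0, rho=0.0, s_beta_MB=0.0,
                                  s_beta_MF=0.0, s_rho=0.0, s_eta1=0.0,
                                  s_eta2=0.0, s_beta_2=0.0)
        spec.group_sds = {}
        df = synthetic.simulate_twostep_cohort(spec, model="softmax_hybrid")
        _, coef = stay_probability_analysis(df)
        c = coef.set_index("term")
        assert c.loc["prev_reward_c", "estimate"] > 0
        assert c.loc["prev_reward_c", "z"] > 2


class TestContextGLMMs:
    def test_null_context_effect_on_choice(self):
        design = synthetic.make_discounting_design(1, (0, 1), seed=21)
        spec = synthetic.CohortSpec(12, dict(k_log=-3.5, beta=0.4), {"k_log": 0.7},
                                    seed=22)
        df = synthetic.simulate_discounting_cohort(spec, design, "softmax")
        coef = context_glmms(df).set_index("term")
        assert abs(coef.loc["context", "z"]) < 2.5

    def test_positive_k_shift_gives_negative_context_coefficient(self):
        design = synthetic.make_discounting_design(1, (0, 1), seed=23)
        spec = synthetic.CohortSpec(12, dict(k_log=-3.5, beta=0.4, s_k_log=1.0),
                                    {"k_log": 0.7}, seed=24)
        df = synthetic.simulate_discounting_cohort(spec, design, "softmax")
        coef = context_glmms(df).set_index("term")
        assert coef.loc["context", "estimate"] < 0
        assert coef.loc["context", "z"] < -2

    def test_planted_rare_transition_slowing_recovered(self):
        rng = np.random.default_rng(25)
        n = 240
        rows = []
        for s in range(8):
            tr = rng.integers(0, 2, n)
            rt = 0.6 + 0.12 * tr + 0.05 * rng.standard_normal(n)
            rows.append(pd.DataFrame(dict(subject=s, context=rng.integers(0, 2, n),
                                          transition=tr, rt_s2=rt)))
        df = pd.concat(rows, ignore_index=True)
        coef = context_glmms(df, task="twostep").set_index("term")
        assert coef.loc["transition", "estimate"] == pytest.approx(0.12, abs=0.02)
        assert coef.loc["transition", "p"] < 1e-6

    def test_single_context_rejected(self):
        design = synthetic.make_discounting_design(1, (0, 0), seed=26)
        spec = synthetic.CohortSpec(3, dict(k_log=-3.5, beta=0.4), {}, seed=27)
        df = synthetic.simulate_discounting_cohort(spec, design, "softmax")
        with pytest.raises(ValueError, match="context"):
            context_glmms(df)
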