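"""Hybrid MF/MB learner: value updates, decay, choice rules, preprocessing."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctxddm.twostep import (
    QState,
    TwoStepTrial,
    decay_unchosen,
    init_qstate,
    mb_values,
    mf_update,
    preprocess_twostep_rts,
    rlddm_drifts,
    s1_choice_probability,
    s2_choice_probability,
    twostep_loglik,
)


def _trial(a1=0, s2=0, a2=0, r=0.5):
    return TwoStepTrial(s1_action=a1, transition=0, s2_state=s2, s2_action=a2, reward=r)


class TestMFUpdate:
    def test_hand_worked_update(self):
        """delta_S2 = 0.4 -> Q_S2 0.7; delta_S1 uses pre-update Q_S2 -> Q_S1 0.62."""
        st_ = init_qstate()
        st_.q_mf_s1[:] = 0.4
        st_.q_mf_s2[:] = 0.5
        out = mf_update(st_, _trial(r=0.9), dict(eta1=0.2, eta2=0.5), I=0)
        assert out.q_mf_s2[0, 0] == pytest.approx(0.7)
        assert out.q_mf_s1[0] == pytest.approx(0.62)

    def test_zero_prediction_errors_change_nothing(self):
        st_ = init_qstate()
        st_.q_mf_s1[:] = 0.5
        out = mf_update(st_, _trial(r=0.5), dict(eta1=0.3, eta2=0.7))
        np.testing.assert_allclose(out.q_mf_s1, st_.q_mf_s1)
        np.testing.assert_allclose(out.q_mf_s2, st_.q_mf_s2)

    def test_zero_learning_rates_change_nothing(self):
        st_ = init_qstate()
        st_.q_mf_s1[:] = [0.2, 0.9]
        st_.q_mf_s2[0] = [0.1, 0.8]
        out = mf_update(st_, _trial(r=1.0), dict(eta1=0.0, eta2=0.0))
        np.testing.assert_allclose(out.q_mf_s1, st_.q_mf_s1)

    def test_rate_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            mf_update(init_qstate(), _trial(), dict(eta1=1.3, eta2=0.5))


class TestMBValues:
    def test_uniform_environment(self):
        st_ = init_qstate()
        st_.q_mf_s2[:] = 0.4
        np.testing.assert_allclose(mb_values(st_, 0.7), [0.4, 0.4])

    def test_bellman_weighting(self):
        st_ = init_qstate()
        st_.q_mf_s2[0] = [0.8, 0.1]
        st_.q_mf_s2[1] = [0.2, 0.4]
        np.testing.assert_allclose(mb_values(st_, 0.7), [0.68, 0.52])

    def test_symmetric_transitions_equalize(self):
        st_ = init_qstate()
        st_.q_mf_s2[0] = [0.9, 0.0]
        st_.q_mf_s2[1] = [0.3, 0.35]
        v = mb_values(st_, 0.5)
        assert v[0] == pytest.approx(v[1])


class TestDecay:
    def test_rate_one_is_identity(self):
        st_ = init_qstate()
        st_.q_mf_s2[:] = [[0.9, 0.1], [0.3, 0.7]]
        out = decay_unchosen(st_, _trial(), dict(eta_decay=1.0))
        np.testing.assert_allclose(out.q_mf_s2, st_.q_mf_s2)

    def test_walk_mean_is_fixed_point(self):
        st_ = init_qstate()  # everything at 0.5
        out = decay_unchosen(st_, _trial(), dict(eta_decay=0.3))
        np.testing.assert_allclose(out.q_mf_s2, 0.5)

    def test_decay_arithmetic_and_chosen_untouched(self):
        st_ = init_qstate()
        st_.q_mf_s2[:] = 0.9
        out = decay_unchosen(st_, _trial(a1=0, s2=0, a2=0), dict(eta_decay=0.8))
        assert out.q_mf_s2[0, 0] == pytest.approx(0.9)  # chosen
        assert out.q_mf_s2[0, 1] == pytest.approx(0.82)  # 0.72 + 0.1
        assert out.q_mf_s2[1, 0] == pytest.approx(0.82)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(q=st.floats(0.0, 1.0), rate=st.floats(0.0, 1.0))
    def test_contraction_toward_half(self, q, rate):
        st_ = init_qstate()
        st_.q_mf_s2[1, 1] = q
        out = decay_unchosen(st_, _trial(), dict(eta_decay=rate))
        assert abs(out.q_mf_s2[1, 1] - 0.5) == pytest.approx(rate * abs(q - 0.5))


class TestChoiceRules:
    def test_zero_weights_are_uniform(self):
        p = s1_choice_probability(init_qstate(), dict(beta_MB=0, beta_MF=0, rho=0))
        np.testing.assert_allclose(p, [0.5, 0.5])
        assert p.sum() == pytest.approx(1.0)

    def test_perseveration_logistic(self):
        # equal Q values, rho = ln 3 -> p(repeat) = 3/4
        p = s1_choice_probability(
            init_qstate(), dict(beta_MB=1.0, beta_MF=1.0, rho=math.log(3.0)),
            prev_action=1,
        )
        assert p[1] == pytest.approx(0.75)

    def test_s2_softmax(self):
        st_ = init_qstate()
        st_.q_mf_s2[0] = [0.3, 0.8]
        p = s2_choice_probability(st_, dict(beta_2=2.0), s2_state=0)
        assert p[1] == pytest.approx(1 / (1 + math.exp(-1)))
        p_flat = s2_choice_probability(init_qstate(), dict(beta_2=7.0), s2_state=1)
        np.testing.assert_allclose(p_flat, [0.5, 0.5])


class TestRLDDMDrifts:
    def test_flat_values_zero_drift(self):
        v1, v2 = rlddm_drifts(init_qstate(), dict(vcoeff_mf=2, vcoeff_mb=3,
                                                  vcoeff_s2=1, rho=0.0))
        assert v1 == 0.0 and v2 == 0.0

    def test_linear_drift_arithmetic(self):
        st_ = init_qstate()
        st_.q_mf_s2[0] = [0.5, 0.5]
        st_.q_mf_s2[1] = [0.8, 0.5]  # state maxima 0.5, 0.8 -> dQ_MB = 0.3*0.4...
        # construct dQ_MB = 0.3 directly: maxima (0.5, 0.8), p_common 0.7
        # qmb = (0.7*0.5+0.3*0.8, 0.7*0.8+0.3*0.5) -> diff = 0.4*0.3 = 0.12
        st_.q_mf_s1[:] = [0.4, 0.5]
        v1, _ = rlddm_drifts(st_, dict(vcoeff_mf=1.0, vcoeff_mb=2.0, vcoeff_s2=0, rho=0.0))
        assert v1 == pytest.approx(2.0 * 0.12 + 1.0 * 0.1)

    def test_sigmoid_variant_bounded_by_vmax(self):
        st_ = init_qstate()
        st_.q_mf_s1[:] = [0.0, 1.0]
        st_.q_mf_s2[0] = [0.0, 0.0]
        st_.q_mf_s2[1] = [1.0, 1.0]
        params = dict(vcoeff_mf=50, vcoeff_mb=50, vcoeff_s2=50, rho=0,
                      vmax_s1=1.5, vmax_s2=2.5)
        v1, v2 = rlddm_drifts(st_, params, variant="s", s2_state=1)
        assert abs(v1) <= 1.5 and abs(v2) <= 2.5


class TestPreprocessing:
    @staticmethod
    def _table(n, rt_lo=0.3):
        rng = np.random.default_rng(8)
        return pd.DataFrame(
            dict(
                subject=0,
                context=0,
                rt_s1=np.sort(rng.uniform(rt_lo, 2.0, n)),
                rt_s2=np.sort(rng.uniform(rt_lo, 2.0, n)),
            )
        )

    def test_percentile_masks_per_stage(self):
        out = preprocess_twostep_rts(self._table(200))
        assert out["use_rt_s1"].sum() == 190
        assert out["use_rt_s2"].sum() == 190
        assert len(out) == 200  # trials stay; only likelihood masks change

    def test_fast_rt_floor(self):
        df = self._table(100)
        df.loc[50, "rt_s1"] = 0.100
        out = preprocess_twostep_rts(df)
        assert out.loc[50, "use_rt_s1"] == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            preprocess_twostep_rts(pd.DataFrame(columns=["subject", "rt_s1", "rt_s2"]))


def _rollout_df(n=60, seed=0, context=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        dict(
            subject=0,
            context=context,
            trial=np.arange(n),
            s1_choice=rng.integers(0, 2, n),
            transition=rng.integers(0, 2, n),
            s2_state=rng.integers(0, 2, n),
            s2_choice=rng.integers(0, 2, n),
            reward=rng.uniform(0, 1, n),
        )
    )


class TestLoglik:
    def test_uniform_agent_chance_level(self):
        df = _rollout_df(70)
        p = dict(eta1=0.3, eta2=0.4, eta_decay=0.8, beta_MB=0, beta_MF=0,
                 beta_2=0, rho=0)
        ll = twostep_loglik("softmax_hybrid", p, df)
        assert ll.sum() == pytest.approx(2 * 70 * math.log(0.5))

    def test_no_shift_likelihood_ignores_context(self):
        df0 = _rollout_df(50, seed=3, context=0)
        df1 = df0.assign(context=1)
        p = dict(eta1=0.4, eta2=0.5, eta_decay=0.7, beta_MB=3, beta_MF=2,
                 beta_2=4, rho=0.5)
        np.testing.assert_allclose(
            twostep_loglik("softmax_hybrid", p, df0),
            twostep_loglik("softmax_hybrid", p, df1),
        )

    def test_mb_dominant_data_prefers_mb_weights(self):
        from ctxddm import synthetic

        spec = synthetic.CohortSpec(
            n_subjects=2,
            group_means=dict(eta1=0.4, eta2=0.5, eta_decay=0.7, beta_MB=6.0,
                             beta_MF=0.5, beta_2=5.0, rho=0.2),
            group_sds={},
            seed=5,
        )
        df = synthetic.simulate_twostep_cohort(spec, model="softmax_hybrid")
        good = twostep_loglik("softmax_hybrid", spec.group_means, df).sum()
        swapped = dict(spec.group_means, beta_MB=0.5, beta_MF=6.0)
        assert good > twostep_loglik("softmax_hybrid", swapped, df).sum()

    def test_q_values_stay_bounded_when_s1_rate_dominates(self):
        """With eta1 >= eta2 the S1 hybrid update is a convex combination, so
        all Q values remain in [0, 1] along any rollout (the guarantee does
        not hold for eta2 > eta1; see the methods note)."""
        rng = np.random.default_rng(11)
        for rep in range(5):
            e2 = rng.uniform(0, 1)
            e1 = rng.uniform(e2, 1)
            params = dict(eta1=e1, eta2=e2, eta_decay=rng.uniform(0, 1))
            state = init_qstate()
            for t in range(200):
                tr = _trial(a1=rng.integers(0, 2), s2=rng.integers(0, 2),
                            a2=rng.integers(0, 2), r=rng.uniform(0, 1))
                state = decay_unchosen(mf_update(state, tr, params), tr, params)
                assert np.all(state.q_mf_s1 >= -1e-12) and np.all(state.q_mf_s1 <= 1 + 1e-12)
                assert np.all(state.q_mf_s2 >= -1e-12) and np.all(state.q_mf_s2 <= 1 + 1e-12)
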