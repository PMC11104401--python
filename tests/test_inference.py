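"""WAIC, directional Bayes factors, model comparison and the fit contract."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from ctxddm import synthetic
from ctxddm.inference import (
    MCMCSettings,
    PriorSpec,
    compare_models,
    compute_waic,
    directional_bf,
    evidence_band,
    fit_hierarchical,
    fit_shift_covariate_model,
)
from ctxddm.registry import get_model


class TestWAIC:
    def test_single_trial_hand_computation(self):
        # all draws at log 0.5 -> p_waic = 0, WAIC = -2 log 0.5
        ll = np.full((100, 1), np.log(0.5))
        w = compute_waic(ll)
        assert w.p_waic == pytest.approx(0.0)
        assert w.waic == pytest.approx(-2 * np.log(0.5))

    def test_duplicating_trials_doubles_waic(self):
        rng = np.random.default_rng(0)
        ll = -np.abs(rng.normal(1.0, 0.3, size=(200, 40)))
        w1 = compute_waic(ll)
        w2 = compute_waic(np.concatenate([ll, ll], axis=1))
        assert w2.waic == pytest.approx(2 * w1.waic)
        assert w2.p_waic == pytest.approx(2 * w1.p_waic)

    def test_zero_variance_draws_have_no_effective_parameters(self):
        ll = np.tile(-np.linspace(0.5, 2.0, 30), (50, 1))
        assert compute_waic(ll).p_waic == pytest.approx(0.0)

    def test_agrees_with_arviz_reference(self):
        """Independent-oracle check of the textbook formula at 1e-10."""
        import arviz as az

        rng = np.random.default_rng(7)
        ll = rng.normal(-1.2, 0.4, size=(2 * 150, 60))
        ours = compute_waic(ll)
        idata = az.from_dict(log_likelihood={"y": ll.reshape(2, 150, 60)})
        ref = az.waic(idata, scale="deviance")
        # arviz computes the pointwise variance with ddof=0; the textbook
        # (ddof=1) quantities relate to it exactly
        S = ll.shape[0]
        assert ours.p_waic == pytest.approx(float(ref.p_waic) * S / (S - 1), abs=1e-10)
        assert -2 * ours.lppd == pytest.approx(
            float(ref.elpd_waic) - 2 * float(ref.p_waic), abs=1e-8
        )

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            compute_waic(np.zeros((1, 10)))
        with pytest.raises(ValueError):
            compute_waic(np.full((5, 3), -np.inf))


class TestDirectionalBF:
    def test_symmetric_draws_give_unit_bf(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.0, 1.0, 40000)
        x = np.concatenate([x, -x])  # exactly symmetric
        assert directional_bf(x).value == pytest.approx(1.0, abs=0.05)

    def test_normal_one_one_matches_cdf_ratio(self):
        rng = np.random.default_rng(2)
        x = rng.normal(1.0, 1.0, 50000)
        oracle = norm.cdf(1) / norm.cdf(-1)  # ~ 5.30
        assert directional_bf(x).value == pytest.approx(oracle, rel=0.07)

    def test_reciprocal_property(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.6, 0.8, 20000)
        bf = directional_bf(x).value
        assert directional_bf(-x).value == pytest.approx(1.0 / bf, rel=0.05)

    def test_invariant_to_draw_order(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.3, 1.0, 5000)
        assert directional_bf(np.sort(x)).value == pytest.approx(
            directional_bf(x[::-1]).value
        )

    def test_one_sided_draws_capped(self):
        res = directional_bf(np.abs(np.random.default_rng(5).normal(2, 0.1, 500)))
        assert res.capped and np.isinf(res.value)

    def test_evidence_bands(self):
        assert evidence_band(2.0) == "anecdotal"
        assert evidence_band(5.0) == "moderate"
        assert evidence_band(15.0) == "strong"
        assert evidence_band(50.0) == "very strong"
        assert evidence_band(500.0) == "extreme"
        assert evidence_band(1 / 15.0) == "strong"  # reciprocals mirror


def _tiny_fit(seed=0, n_subjects=6, **mcmc_kw):
    design = synthetic.make_discounting_design(1, (0, 1), seed=seed)
    spec = synthetic.default_cohort_spec("softmax", n_subjects, seed)
    df = synthetic.simulate_discounting_cohort(spec, design, "softmax")
    settings = MCMCSettings(chains=2, burn_in=150, draws=200, thin=2,
                            max_extensions=0, **mcmc_kw)
    return df, fit_hierarchical("softmax", df, mcmc=settings, seed=seed + 1)


class TestFitContract:
    def test_posterior_samples_shape_and_summary(self):
        df, fit = _tiny_fit(seed=10)
        assert fit.group_mean.shape == (2, 100, 4)
        assert fit.subject.shape == (2, 100, 6, 4)
        assert np.all(np.isfinite(fit.group_mean))
        s = fit.summary()
        assert set(s["parameter"]) == {"k_log", "beta", "s_k_log", "s_beta"}
        assert {"hdi85_low", "hdi95_high", "rhat", "directional_bf"} <= set(s.columns)
        # shift rows carry directional BFs, baselines do not
        assert s.set_index("parameter")["directional_bf"].loc[["s_k_log", "s_beta"]].notna().all()

    def test_rhat_reported_and_identical_seeds_reproduce(self):
        df, fit1 = _tiny_fit(seed=20)
        _, fit2 = _tiny_fit(seed=20)
        assert "mu_k_log" in fit1.rhat and "subject_max" in fit1.rhat
        np.testing.assert_array_equal(fit1.group_mean, fit2.group_mean)
        np.testing.assert_array_equal(fit1.pointwise_loglik, fit2.pointwise_loglik)

    def test_comparing_fit_to_itself_gives_zero_difference(self):
        df, fit = _tiny_fit(seed=30)
        table = compare_models([fit, fit])
        assert table["d_waic"].iloc[1] == pytest.approx(0.0)
        assert table["d_se"].iloc[1] == pytest.approx(0.0)

    def test_fingerprint_mismatch_rejected(self):
        _, fit1 = _tiny_fit(seed=40)
        _, fit2 = _tiny_fit(seed=41)
        with pytest.raises(ValueError, match="fingerprint"):
            compare_models([fit1, fit2])

    def test_prior_spec_covers_every_parameter(self):
        for name in ("softmax", "ddm_s", "softmax_hybrid", "rlddm_s"):
            spec = get_model(name)
            pr = PriorSpec.for_model(spec)
            assert pr.lo.shape == (len(spec.params),)
            assert np.all(pr.hi > pr.lo)
            assert np.all(pr.shift_sd > 0)


class TestCovariateExtension:
    def test_slope_recovery_and_permutation_control(self):
        """A planted covariate effect on the discount-rate shift is recovered;
        permuting covariate rows against subjects destroys it."""
        rng = np.random.default_rng(6)
        n = 16
        design = synthetic.make_discounting_design(1, (0, 1), seed=3)
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std()
        rows = []
        for s in range(n):
            spec = synthetic.CohortSpec(
                1,
                dict(k_log=-3.5 + 0.5 * rng.standard_normal(),
                     beta=0.4, s_k_log=0.4 + 0.5 * x[s]),
                {},
                seed=100 + s,
            )
            sub = synthetic.simulate_discounting_cohort(spec, design, "softmax")
            sub["subject"] = s
            rows.append(sub)
        df = pd.concat(rows, ignore_index=True)
        cov = pd.DataFrame(dict(subject=range(n), grcs=x))
        settings = MCMCSettings(chains=2, burn_in=400, draws=500, thin=2,
                                max_extensions=0)
        fit = fit_shift_covariate_model("softmax", df, cov, mcmc=settings, seed=9)
        slope = fit.slopes.reshape(-1)
        assert slope.mean() == pytest.approx(0.5, abs=0.25)
        # negative control: permuted covariates
        cov_perm = cov.assign(grcs=np.roll(x, 5))
        fit_p = fit_shift_covariate_model("softmax", df, cov_perm,
                                          mcmc=settings, seed=9)
        slope_p = fit_p.slopes.reshape(-1)
        lo, hi = np.quantile(slope_p, [0.025, 0.975])
        assert lo < 0 < hi

    def test_covariate_subject_mismatch_rejected(self):
        df, _fit = _tiny_fit(seed=50)
        cov = pd.DataFrame(dict(subject=[100, 101], grcs=[0.0, 1.0]))
        with pytest.raises(ValueError, match="covariate"):
            fit_shift_covariate_model("softmax", df, cov,
                                      mcmc=MCMCSettings(chains=2, burn_in=10,
                                                        draws=10, thin=1,
                                                        max_extensions=0),
                                      seed=1)
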