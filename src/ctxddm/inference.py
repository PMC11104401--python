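"""Hierarchical Bayesian estimation, model comparison and directional BFs.

Every model in the registry is fit with separate group-level Gaussian
distributions for each baseline parameter and each context-shift parameter:
subject-level values are drawn from ``Normal(mu_p, sigma_p)`` restricted to
the declared support, baseline group means get uniform priors over plausible
ranges, shift group means get zero-centered Gaussian priors, and group SDs
get half-Cauchy priors.  Sampling is adaptive Metropolis-within-Gibbs:
single-site random-walk proposals for every group- and subject-level
parameter, with proposal scales tuned toward a 0.44 acceptance rate during
burn-in and frozen afterwards.  Convergence is gated on the rank-normalized
split-chain R-hat (<= 1.02 by default); non-converged fits are flagged and
reported, not silently passed.

Model comparison uses WAIC computed from pointwise posterior log-likelihoods;
context effects are summarized by directional Bayes factors — the ratio of
posterior mass above zero to mass below zero of a shift parameter's
group-mean posterior, estimated by Gaussian kernel density.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import gaussian_kde

from .discounting import _disc_loglik_sum, _disc_pointwise, _trials_to_arrays
from .registry import ModelSpec, get_model
from .twostep import _two_loglik_sum, _two_pointwise, _twostep_arrays

logger = logging.getLogger("ctxddm")

__all__ = [
    "MCMCSettings",
    "PriorSpec",
    "PosteriorSamples",
    "DirectionalBF",
    "WAICResult",
    "fit_hierarchical",
    "fit_shift_covariate_model",
    "compute_waic",
    "directional_bf",
    "evidence_band",
    "compare_models",
    "run_parameter_recovery",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class MCMCSettings:
    """Sampler settings; paper-scale values are the defaults, tests scale down."""

    chains: int = 2
    burn_in: int = 1000
    draws: int = 2000
    thin: int = 2
    rhat_gate: float = 1.02
    max_extensions: int = 1
    adapt_interval: int = 50
    pointwise_max_draws: int = 1000


def load_default_priors() -> dict:
    import importlib.resources

    import yaml

    with importlib.resources.files("ctxddm").joinpath("default_priors.yaml").open() as f:
        return yaml.safe_load(f)


@dataclass
class PriorSpec:
    """Numeric prior hyperparameters bound to one model's parameter vector."""

    lo: np.ndarray  # uniform range / support, baselines
    hi: np.ndarray
    shift_sd: np.ndarray  # SD of the zero-centered shift group-mean priors
    sigma_scale: float = 2.5  # half-Cauchy scale of the group SDs

    @classmethod
    def for_model(cls, spec: ModelSpec, config: dict | None = None) -> "PriorSpec":
        cfg = config if config is not None else load_default_priors()
        lo, hi = spec.low_high()
        tab = cfg.get("shift_prior_sd", {})
        default_sd = float(tab.get("default", 1.0))
        shift_sd = np.array([float(tab.get(p, default_sd)) for p in spec.params])
        return cls(lo=lo, hi=hi, shift_sd=shift_sd,
                   sigma_scale=float(cfg.get("sigma_half_cauchy_scale", 2.5)))


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------


@dataclass
class WAICResult:
    waic: float
    p_waic: float
    lppd: float
    se: float
    pointwise: np.ndarray  # per-trial -2 * elpd contributions


@dataclass
class DirectionalBF:
    """Posterior mass ratio P(shift > 0) / P(shift < 0) with evidence band."""

    value: float
    band: str
    direction: str  # "positive" | "negative"
    capped: bool = False


@dataclass
class PosteriorSamples:
    model: str
    param_names: tuple[str, ...]
    group_mean: np.ndarray  # (chains, kept, 2P)
    group_sd: np.ndarray  # (chains, kept, 2P)
    subject: np.ndarray  # (chains, kept, S, 2P)
    pointwise_loglik: np.ndarray  # (draws_used, n_trials)
    rhat: dict
    converged: bool
    meta: dict
    slopes: np.ndarray | None = None  # (chains, kept, n_cov)
    cov_names: tuple[str, ...] = ()

    def _pidx(self, name: str) -> int:
        return self.param_names.index(name)

    def group_mean_draws(self, name: str) -> np.ndarray:
        return self.group_mean[:, :, self._pidx(name)].reshape(-1)

    def group_sd_draws(self, name: str) -> np.ndarray:
        return self.group_sd[:, :, self._pidx(name)].reshape(-1)

    def subject_means(self) -> np.ndarray:
        """Posterior-mean subject-level parameters, shape (S, 2P)."""
        return self.subject.mean(axis=(0, 1))

    def subject_medians(self) -> np.ndarray:
        c, k, s, p = self.subject.shape
        return np.median(self.subject.reshape(c * k, s, p), axis=0)

    def summary(self) -> pd.DataFrame:
        """Posterior summary table (means, SDs, HDIs, R-hat, directional BFs)."""
        rows = []
        for j, name in enumerate(self.param_names):
            flat = self.group_mean[:, :, j].reshape(-1)
            h85 = az.hdi(flat, hdi_prob=0.85)
            h95 = az.hdi(flat, hdi_prob=0.95)
            bf = np.nan
            if name.startswith("s_"):
                bf = directional_bf(flat).value
            rows.append(
                dict(
                    parameter=name,
                    mean=flat.mean(),
                    sd=flat.std(ddof=1),
                    hdi85_low=h85[0],
                    hdi85_high=h85[1],
                    hdi95_low=h95[0],
                    hdi95_high=h95[1],
                    rhat=self.rhat.get(f"mu_{name}", np.nan),
                    directional_bf=bf,
                )
            )
        if self.slopes is not None:
            for j, name in enumerate(self.cov_names):
                flat = self.slopes[:, :, j].reshape(-1)
                h85 = az.hdi(flat, hdi_prob=0.85)
                h95 = az.hdi(flat, hdi_prob=0.95)
                rows.append(
                    dict(
                        parameter=f"slope_{name}",
                        mean=flat.mean(),
                        sd=flat.std(ddof=1),
                        hdi85_low=h85[0],
                        hdi85_high=h85[1],
                        hdi95_low=h95[0],
                        hdi95_high=h95[1],
                        rhat=self.rhat.get(f"slope_{name}", np.nan),
                        directional_bf=directional_bf(flat).value,
                    )
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# subject-level MH sweeps (numba)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _update_subjects_disc(model_id, theta, MU, SIG, scales, lo, hi,
                          A, D, I, C, RT, nT, cur_ll, seed):
    np.random.seed(seed)
    S, P2 = theta.shape
    P = P2 // 2
    acc = np.zeros((S, P2))
    for s in range(S):
        for p in range(P2):
            old = theta[s, p]
            prop = old + scales[s, p] * np.random.randn()
            pb = p % P
            if p < P:
                e0 = prop
                e1 = prop + theta[s, p + P]
            else:
                e0 = theta[s, p - P]
                e1 = theta[s, p - P] + prop
            if e0 < lo[pb] or e0 > hi[pb] or e1 < lo[pb] or e1 > hi[pb]:
                continue
            theta[s, p] = prop
            ll = _disc_loglik_sum(model_id, theta[s], A[s], D[s], I[s], C[s], RT[s], nT[s])
            dp = (-0.5 * ((prop - MU[s, p]) / SIG[p]) ** 2
                  + 0.5 * ((old - MU[s, p]) / SIG[p]) ** 2)
            delta = ll - cur_ll[s] + dp
            if np.isinf(ll) and np.isinf(cur_ll[s]):
                delta = dp  # both states impossible: move by the prior alone
            if math.log(np.random.rand()) < delta:
                cur_ll[s] = ll
                acc[s, p] = 1.0
            else:
                theta[s, p] = old
    return acc


@njit(cache=True)
def _update_subjects_two(model_id, theta, MU, SIG, scales, lo, hi,
                         a1, s2, a2, r, I, rt1, rt2, u1, u2, reset, nT,
                         p_common, cur_ll, seed):
    np.random.seed(seed)
    S, P2 = theta.shape
    P = P2 // 2
    acc = np.zeros((S, P2))
    for s in range(S):
        for p in range(P2):
            old = theta[s, p]
            prop = old + scales[s, p] * np.random.randn()
            pb = p % P
            if p < P:
                e0 = prop
                e1 = prop + theta[s, p + P]
            else:
                e0 = theta[s, p - P]
                e1 = theta[s, p - P] + prop
            if e0 < lo[pb] or e0 > hi[pb] or e1 < lo[pb] or e1 > hi[pb]:
                continue
            theta[s, p] = prop
            ll = _two_loglik_sum(model_id, theta[s], a1[s], s2[s], a2[s], r[s],
                                 I[s], rt1[s], rt2[s], u1[s], u2[s], reset[s],
                                 nT[s], p_common)
            dp = (-0.5 * ((prop - MU[s, p]) / SIG[p]) ** 2
                  + 0.5 * ((old - MU[s, p]) / SIG[p]) ** 2)
            delta = ll - cur_ll[s] + dp
            if np.isinf(ll) and np.isinf(cur_ll[s]):
                delta = dp  # both states impossible: move by the prior alone
            if math.log(np.random.rand()) < delta:
                cur_ll[s] = ll
                acc[s, p] = 1.0
            else:
                theta[s, p] = old
    return acc


@njit(cache=True)
def _joint_update_disc(model_id, theta, MU, SIG, L, eps, lo, hi,
                       A, D, I, C, RT, nT, cur_ll, seed):
    """Per-subject full-vector proposal from the empirical covariance."""
    np.random.seed(seed)
    S, P2 = theta.shape
    P = P2 // 2
    acc = np.zeros(S)
    for s in range(S):
        step = eps * (L[s] @ np.random.randn(P2))
        prop = theta[s] + step
        ok = True
        for pb in range(P):
            e0 = prop[pb]
            e1 = prop[pb] + prop[pb + P]
            if e0 < lo[pb] or e0 > hi[pb] or e1 < lo[pb] or e1 > hi[pb]:
                ok = False
                break
        if not ok:
            continue
        dp = 0.0
        for p in range(P2):
            dp += (-0.5 * ((prop[p] - MU[s, p]) / SIG[p]) ** 2
                   + 0.5 * ((theta[s, p] - MU[s, p]) / SIG[p]) ** 2)
        old = theta[s].copy()
        theta[s] = prop
        ll = _disc_loglik_sum(model_id, theta[s], A[s], D[s], I[s], C[s], RT[s], nT[s])
        delta = ll - cur_ll[s] + dp
        if np.isinf(ll) and np.isinf(cur_ll[s]):
            delta = dp
        if math.log(np.random.rand()) < delta:
            cur_ll[s] = ll
            acc[s] = 1.0
        else:
            theta[s] = old
    return acc


@njit(cache=True)
def _joint_update_two(model_id, theta, MU, SIG, L, eps, lo, hi,
                      a1, s2, a2, r, I, rt1, rt2, u1, u2, reset, nT,
                      p_common, cur_ll, seed):
    np.random.seed(seed)
    S, P2 = theta.shape
    P = P2 // 2
    acc = np.zeros(S)
    for s in range(S):
        step = eps * (L[s] @ np.random.randn(P2))
        prop = theta[s] + step
        ok = True
        for pb in range(P):
            e0 = prop[pb]
            e1 = prop[pb] + prop[pb + P]
            if e0 < lo[pb] or e0 > hi[pb] or e1 < lo[pb] or e1 > hi[pb]:
                ok = False
                break
        if not ok:
            continue
        dp = 0.0
        for p in range(P2):
            dp += (-0.5 * ((prop[p] - MU[s, p]) / SIG[p]) ** 2
                   + 0.5 * ((theta[s, p] - MU[s, p]) / SIG[p]) ** 2)
        old = theta[s].copy()
        theta[s] = prop
        ll = _two_loglik_sum(model_id, theta[s], a1[s], s2[s], a2[s], r[s],
                             I[s], rt1[s], rt2[s], u1[s], u2[s], reset[s],
                             nT[s], p_common)
        delta = ll - cur_ll[s] + dp
        if np.isinf(ll) and np.isinf(cur_ll[s]):
            delta = dp
        if math.log(np.random.rand()) < delta:
            cur_ll[s] = ll
            acc[s] = 1.0
        else:
            theta[s] = old
    return acc


@njit(cache=True)
def _indep_update_disc(model_id, theta, MU, SIG, c, lo, hi,
                       A, D, I, C, RT, nT, cur_ll, seed):
    """Independence proposals from the group prior (mode jumping)."""
    np.random.seed(seed)
    S, P2 = theta.shape
    P = P2 // 2
    acc = np.zeros(S)
    for s in range(S):
        prop = np.empty(P2)
        for p in range(P2):
            prop[p] = MU[s, p] + c * SIG[p] * np.random.randn()
        ok = True
        for pb in range(P):
            e0 = prop[pb]
            e1 = prop[pb] + prop[pb + P]
            if e0 < lo[pb] or e0 > hi[pb] or e1 < lo[pb] or e1 > hi[pb]:
                ok = False
                break
        if not ok:
            continue
        # prior ratio + Hastings correction for the Normal(MU, c*SIG) proposal
        dp = 0.0
        for p in range(P2):
            z_new = (prop[p] - MU[s, p]) / SIG[p]
            z_old = (theta[s, p] - MU[s, p]) / SIG[p]
            dp += -0.5 * z_new * z_new + 0.5 * z_old * z_old
            dp += (-0.5 * (z_old / c) ** 2 + 0.5 * (z_new / c) ** 2)
        old = theta[s].copy()
        theta[s] = prop
        ll = _disc_loglik_sum(model_id, theta[s], A[s], D[s], I[s], C[s], RT[s], nT[s])
        delta = ll - cur_ll[s] + dp
        if np.isinf(ll) and np.isinf(cur_ll[s]):
            delta = dp
        if math.log(np.random.rand()) < delta:
            cur_ll[s] = ll
            acc[s] = 1.0
        else:
            theta[s] = old
    return acc


@njit(cache=True)
def _indep_update_two(model_id, theta, MU, SIG, c, lo, hi,
                      a1, s2, a2, r, I, rt1, rt2, u1, u2, reset, nT,
                      p_common, cur_ll, seed):
    np.random.seed(seed)
    S, P2 = theta.shape
    P = P2 // 2
    acc = np.zeros(S)
    for s in range(S):
        prop = np.empty(P2)
        for p in range(P2):
            prop[p] = MU[s, p] + c * SIG[p] * np.random.randn()
        ok = True
        for pb in range(P):
            e0 = prop[pb]
            e1 = prop[pb] + prop[pb + P]
            if e0 < lo[pb] or e0 > hi[pb] or e1 < lo[pb] or e1 > hi[pb]:
                ok = False
                break
        if not ok:
            continue
        dp = 0.0
        for p in range(P2):
            z_new = (prop[p] - MU[s, p]) / SIG[p]
            z_old = (theta[s, p] - MU[s, p]) / SIG[p]
            dp += -0.5 * z_new * z_new + 0.5 * z_old * z_old
            dp += (-0.5 * (z_old / c) ** 2 + 0.5 * (z_new / c) ** 2)
        old = theta[s].copy()
        theta[s] = prop
        ll = _two_loglik_sum(model_id, theta[s], a1[s], s2[s], a2[s], r[s],
                             I[s], rt1[s], rt2[s], u1[s], u2[s], reset[s],
                             nT[s], p_common)
        delta = ll - cur_ll[s] + dp
        if np.isinf(ll) and np.isinf(cur_ll[s]):
            delta = dp
        if math.log(np.random.rand()) < delta:
            cur_ll[s] = ll
            acc[s] = 1.0
        else:
            theta[s] = old
    return acc


@njit(cache=True)
def _loglik_all_disc(model_id, theta, A, D, I, C, RT, nT, out):
    for s in range(theta.shape[0]):
        out[s] = _disc_loglik_sum(model_id, theta[s], A[s], D[s], I[s], C[s], RT[s], nT[s])


@njit(cache=True)
def _loglik_all_two(model_id, theta, a1, s2, a2, r, I, rt1, rt2, u1, u2, reset,
                    nT, p_common, out):
    for s in range(theta.shape[0]):
        out[s] = _two_loglik_sum(model_id, theta[s], a1[s], s2[s], a2[s], r[s],
                                 I[s], rt1[s], rt2[s], u1[s], u2[s], reset[s],
                                 nT[s], p_common)


@njit(cache=True)
def _pointwise_draws_disc(model_id, TH, A, D, I, C, RT, nT, offsets, out):
    Dn, S, _ = TH.shape
    for d in range(Dn):
        for s in range(S):
            n = nT[s]
            buf = np.empty(n)
            _disc_pointwise(model_id, TH[d, s], A[s], D[s], I[s], C[s], RT[s], n, buf)
            for t in range(n):
                out[d, offsets[s] + t] = buf[t]


@njit(cache=True)
def _pointwise_draws_two(model_id, TH, a1, s2, a2, r, I, rt1, rt2, u1, u2,
                         reset, nT, p_common, offsets, out):
    Dn, S, _ = TH.shape
    for d in range(Dn):
        for s in range(S):
            n = nT[s]
            buf = np.empty(n)
            _two_pointwise(model_id, TH[d, s], a1[s], s2[s], a2[s], r[s], I[s],
                           rt1[s], rt2[s], u1[s], u2[s], reset[s], n, p_common, buf)
            for t in range(n):
                out[d, offsets[s] + t] = buf[t]


# ---------------------------------------------------------------------------
# data packing
# ---------------------------------------------------------------------------


def data_fingerprint(trials: pd.DataFrame) -> str:
    cols = sorted(c for c in trials.columns if not c.startswith("use_rt"))
    payload = trials[cols].round(9).to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _pack_discounting(trials: pd.DataFrame, uses_rt: bool):
    subjects = list(dict.fromkeys(trials["subject"]))
    nT = np.array([(trials["subject"] == s).sum() for s in subjects], dtype=np.int64)
    S, T = len(subjects), int(nT.max())
    A = np.zeros((S, T))
    D = np.zeros((S, T))
    I = np.zeros((S, T), dtype=np.int64)
    C = np.zeros((S, T), dtype=np.int64)
    RT = np.zeros((S, T))
    for si, s in enumerate(subjects):
        sub = trials[trials["subject"] == s]
        a, d, i, c, rt = _trials_to_arrays(sub, uses_rt)
        n = len(sub)
        A[si, :n], D[si, :n], I[si, :n], C[si, :n], RT[si, :n] = a, d, i, c, rt
    return subjects, nT, (A, D, I, C, RT)


def _pack_twostep(trials: pd.DataFrame, uses_rt: bool):
    subjects = list(dict.fromkeys(trials["subject"]))
    nT = np.array([(trials["subject"] == s).sum() for s in subjects], dtype=np.int64)
    S, T = len(subjects), int(nT.max())
    arrs = [np.zeros((S, T), dtype=np.int64) for _ in range(3)]  # a1, s2, a2
    r = np.zeros((S, T))
    I = np.zeros((S, T), dtype=np.int64)
    rt1 = np.zeros((S, T))
    rt2 = np.zeros((S, T))
    u1 = np.zeros((S, T), dtype=np.int64)
    u2 = np.zeros((S, T), dtype=np.int64)
    reset = np.zeros((S, T), dtype=np.int64)
    for si, s in enumerate(subjects):
        sub = trials[trials["subject"] == s]
        a1x, s2x, a2x, rx, Ix, rt1x, rt2x, u1x, u2x, resetx = _twostep_arrays(sub, uses_rt)
        n = len(sub)
        arrs[0][si, :n], arrs[1][si, :n], arrs[2][si, :n] = a1x, s2x, a2x
        r[si, :n], I[si, :n] = rx, Ix
        rt1[si, :n], rt2[si, :n], u1[si, :n], u2[si, :n] = rt1x, rt2x, u1x, u2x
        reset[si, :n] = resetx
    return subjects, nT, (arrs[0], arrs[1], arrs[2], r, I, rt1, rt2, u1, u2, reset)


# ---------------------------------------------------------------------------
# one chain of the sampler
# ---------------------------------------------------------------------------


class _Chain:
    """State + transition kernel of one MCMC chain (Metropolis-within-Gibbs)."""

    def __init__(self, spec, priors, data, nT, p_common, seed, covX=None, cov_pidx=-1):
        self.spec = spec
        self.priors = priors
        self.data = data
        self.nT = nT
        self.p_common = p_common
        self.rng = np.random.default_rng(seed)
        self.base_seed = int(seed)
        self.it = 0
        P = len(spec.params)
        S = len(nT)
        lo, hi = priors.lo, priors.hi
        rngspan = hi - lo
        # group means: baselines near midrange, shifts near 0
        self.mu = np.empty(2 * P)
        self.mu[:P] = (lo + hi) / 2 + 0.1 * rngspan * self.rng.standard_normal(P)
        self.mu[:P] = np.clip(self.mu[:P], lo + 0.05 * rngspan, hi - 0.05 * rngspan)
        self.mu[P:] = 0.02 * self.rng.standard_normal(P)
        self.sig = np.empty(2 * P)
        self.sig[:P] = np.minimum(1.0, 0.15 * rngspan)
        self.sig[P:] = 0.1
        self.theta = np.empty((S, 2 * P))
        for s in range(S):
            base = np.clip(
                self.mu[:P] + 0.5 * self.sig[:P] * self.rng.standard_normal(P),
                lo + 0.02 * rngspan,
                hi - 0.02 * rngspan,
            )
            self.theta[s, :P] = base
            shift = 0.01 * self.rng.standard_normal(P)
            self.theta[s, P:] = np.clip(shift, lo + 0.01 * rngspan - base,
                                        hi - 0.01 * rngspan - base)
        self.covX = covX  # (S, K) standardized covariates or None
        self.cov_pidx = cov_pidx
        self.slopes = (np.zeros(covX.shape[1]) if covX is not None else None)
        # proposal scales
        self.sc_theta = np.empty((S, 2 * P))
        self.sc_theta[:, :P] = 0.2 * np.minimum(1.0, 0.15 * rngspan)
        self.sc_theta[:, P:] = 0.05
        self.sc_mu = np.concatenate([0.05 * rngspan / np.sqrt(S), np.full(P, 0.05)])
        self.sc_sig = np.full(2 * P, 0.3)
        self.sc_slopes = (np.full(covX.shape[1], 0.1) if covX is not None else None)
        # joint-proposal state: per-subject empirical covariance factors
        self.hist: list = []
        self.L = np.zeros((S, 2 * P, 2 * P))
        for s in range(S):
            np.fill_diagonal(self.L[s], self.sc_theta[s])
        self.eps = 1.0
        self.acc_joint = 0.0
        self.n_joint = 0
        # acceptance counters for adaptation
        self._reset_counters()
        self.cur_ll = np.empty(S)
        self._refresh_loglik()
        self._repair_inits(lo, hi, rngspan)
        # start the group level at the (repaired) subject values
        self.mu[:P] = np.clip(self.theta[:, :P].mean(axis=0),
                              lo + 0.02 * rngspan, hi - 0.02 * rngspan)
        self.sig[:P] = np.maximum(self.theta[:, :P].std(axis=0), 0.05 * rngspan)
        self._refresh_loglik()

    def _repair_inits(self, lo, hi, rngspan):
        """Best-of-N random starts per subject.

        The likelihood surfaces of the drift models are multimodal (for
        example a large discount rate with negated drift coefficient mimics
        a near-zero rate); starting every subject at the best of many random
        candidates keeps chains out of mirror modes that single-site and
        covariance proposals cannot cross.
        """
        P = len(self.spec.params)
        S = self.theta.shape[0]
        for s in range(S):
            best_ll = self.cur_ll[s]
            best = self.theta[s].copy()
            for _ in range(60):
                base = self.rng.uniform(lo + 0.05 * rngspan, hi - 0.05 * rngspan)
                self.theta[s, :P] = base
                self.theta[s, P:] = 0.0
                self._refresh_subject_loglik(int(s))
                if not np.isfinite(best_ll) or self.cur_ll[s] > best_ll:
                    best_ll = self.cur_ll[s]
                    best = self.theta[s].copy()
            self.theta[s] = best
            self.cur_ll[s] = best_ll
            if not np.isfinite(best_ll):
                # uniform draws rarely satisfy e.g. tau < fastest RT when many
                # parameters must be feasible at once; retry near the lower
                # bounds, where DDM supports are always feasible
                for _ in range(150):
                    u = self.rng.uniform(0.02, 0.3, P)
                    self.theta[s, :P] = lo + u * rngspan
                    self.theta[s, P:] = 0.0
                    self._refresh_subject_loglik(int(s))
                    if np.isfinite(self.cur_ll[s]):
                        break
                else:
                    logger.warning("subject %d: no finite-likelihood start found", s)

    def _refresh_subject_loglik(self, s: int):
        one = slice(s, s + 1)
        out = np.empty(1)
        if self.spec.task == "discounting":
            _loglik_all_disc(self.spec.model_id, self.theta[one],
                             *[a[one] for a in self.data], self.nT[one], out)
        else:
            _loglik_all_two(self.spec.model_id, self.theta[one],
                            *[a[one] for a in self.data], self.nT[one],
                            self.p_common, out)
        self.cur_ll[s] = out[0]

    # -- likelihood plumbing -------------------------------------------------

    def _refresh_loglik(self):
        if self.spec.task == "discounting":
            _loglik_all_disc(self.spec.model_id, self.theta, *self.data, self.nT, self.cur_ll)
        else:
            _loglik_all_two(self.spec.model_id, self.theta, *self.data, self.nT,
                            self.p_common, self.cur_ll)

    def _prior_means(self):
        """Per-subject group means MU (S, 2P); covariates move one column."""
        S = self.theta.shape[0]
        MU = np.broadcast_to(self.mu, (S, self.mu.size)).copy()
        if self.covX is not None:
            MU[:, self.cov_pidx] = self.mu[self.cov_pidx] + self.covX @ self.slopes
        return MU

    def _reset_counters(self):
        self.n_batch = 0
        self.acc_theta = np.zeros_like(self.sc_theta)
        self.acc_mu = np.zeros_like(self.sc_mu)
        self.acc_sig = np.zeros_like(self.sc_sig)
        self.acc_slopes = (np.zeros_like(self.sc_slopes)
                           if self.sc_slopes is not None else None)

    # -- group-level updates -------------------------------------------------

    def _logprior_mu(self, p, val):
        P = len(self.spec.params)
        if p < P:
            if val < self.priors.lo[p] or val > self.priors.hi[p]:
                return -np.inf
            return 0.0
        sd = self.priors.shift_sd[p - P]
        return -0.5 * (val / sd) ** 2

    def _update_group(self):
        P2 = self.mu.size
        P = P2 // 2
        th = self.theta
        for p in range(P2):
            # group mean
            old = self.mu[p]
            prop = old + self.sc_mu[p] * self.rng.standard_normal()
            lp_new = self._logprior_mu(p, prop)
            if np.isfinite(lp_new):
                if self.covX is not None and p == self.cov_pidx:
                    mean_old = old + self.covX @ self.slopes
                    mean_new = prop + self.covX @ self.slopes
                else:
                    mean_old = old
                    mean_new = prop
                s2 = self.sig[p] ** 2
                d = (np.sum((th[:, p] - mean_old) ** 2) - np.sum((th[:, p] - mean_new) ** 2)) / (2 * s2)
                d += lp_new - self._logprior_mu(p, old)
                if np.log(self.rng.random()) < d:
                    self.mu[p] = prop
                    self.acc_mu[p] += 1
            # group sd (log-scale walk, half-Cauchy prior, Jacobian term)
            old_s = self.sig[p]
            prop_s = old_s * np.exp(self.sc_sig[p] * self.rng.standard_normal())
            if prop_s > 1e-4:
                if self.covX is not None and p == self.cov_pidx:
                    mean = self.mu[p] + self.covX @ self.slopes
                else:
                    mean = self.mu[p]
                ss = np.sum((th[:, p] - mean) ** 2)
                S = th.shape[0]
                def logpost(sg):
                    return (-S * np.log(sg) - ss / (2 * sg * sg)
                            - np.log1p((sg / self.priors.sigma_scale) ** 2)
                            + np.log(sg))  # Jacobian of the log walk
                if np.log(self.rng.random()) < logpost(prop_s) - logpost(old_s):
                    self.sig[p] = prop_s
                    self.acc_sig[p] += 1
        if self.covX is not None:
            p = self.cov_pidx
            s2 = self.sig[p] ** 2
            for j in range(self.slopes.size):
                old = self.slopes[j]
                prop = old + self.sc_slopes[j] * self.rng.standard_normal()
                sl = self.slopes.copy()
                sl[j] = prop
                mean_old = self.mu[p] + self.covX @ self.slopes
                mean_new = self.mu[p] + self.covX @ sl
                d = (np.sum((th[:, p] - mean_old) ** 2)
                     - np.sum((th[:, p] - mean_new) ** 2)) / (2 * s2)
                d += -0.5 * prop ** 2 + 0.5 * old ** 2  # Normal(0,1) prior
                if np.log(self.rng.random()) < d:
                    self.slopes[j] = prop
                    self.acc_slopes[j] += 1

    # -- sweeps --------------------------------------------------------------

    def step(self):
        self.it += 1
        self._update_group()
        MU = self._prior_means()
        seed = (self.base_seed * 7919 + self.it * 104729) % (2**31 - 1)
        if self.spec.task == "discounting":
            acc = _update_subjects_disc(self.spec.model_id, self.theta, MU, self.sig,
                                        self.sc_theta, self.priors.lo, self.priors.hi,
                                        *self.data, self.nT, self.cur_ll, seed)
        else:
            acc = _update_subjects_two(self.spec.model_id, self.theta, MU, self.sig,
                                       self.sc_theta, self.priors.lo, self.priors.hi,
                                       *self.data, self.nT, self.p_common,
                                       self.cur_ll, seed)
        self.acc_theta += acc
        seed2 = (self.base_seed * 104729 + self.it * 7919 + 1) % (2**31 - 1)
        if self.spec.task == "discounting":
            accj = _joint_update_disc(self.spec.model_id, self.theta, MU, self.sig,
                                      self.L, self.eps, self.priors.lo,
                                      self.priors.hi, *self.data, self.nT,
                                      self.cur_ll, seed2)
        else:
            accj = _joint_update_two(self.spec.model_id, self.theta, MU, self.sig,
                                     self.L, self.eps, self.priors.lo,
                                     self.priors.hi, *self.data, self.nT,
                                     self.p_common, self.cur_ll, seed2)
        self.acc_joint += accj.mean()
        self.n_joint += 1
        if self.it % 5 == 0:  # occasional group-prior independence moves
            seed3 = (self.base_seed * 31337 + self.it * 2654435761) % (2**31 - 1)
            if self.spec.task == "discounting":
                _indep_update_disc(self.spec.model_id, self.theta, MU, self.sig,
                                   1.5, self.priors.lo, self.priors.hi,
                                   *self.data, self.nT, self.cur_ll, seed3)
            else:
                _indep_update_two(self.spec.model_id, self.theta, MU, self.sig,
                                  1.5, self.priors.lo, self.priors.hi,
                                  *self.data, self.nT, self.p_common,
                                  self.cur_ll, seed3)
        if self.it % 2 == 0:
            self.hist.append(self.theta.copy())
            if len(self.hist) > 250:
                self.hist.pop(0)
        self.n_batch += 1

    def adapt(self, batch_index):
        """Robbins-Monro style scale adaptation toward 0.44 acceptance."""
        if self.n_batch == 0:
            return
        delta = min(0.25, 1.0 / math.sqrt(batch_index + 1))
        def tune(scales, accepts):
            rate = accepts / self.n_batch
            scales *= np.exp(np.where(rate > 0.44, delta, -delta))
            np.clip(scales, 1e-5, 50.0, out=scales)
        tune(self.sc_theta, self.acc_theta)
        tune(self.sc_mu, self.acc_mu)
        tune(self.sc_sig, self.acc_sig)
        if self.sc_slopes is not None:
            tune(self.sc_slopes, self.acc_slopes)
        # joint-proposal covariance from the recent history (target ~0.25)
        if self.n_joint > 0:
            rate = self.acc_joint / self.n_joint
            self.eps *= math.exp(delta if rate > 0.25 else -delta)
            self.eps = min(max(self.eps, 1e-3), 10.0)
            self.acc_joint = 0.0
            self.n_joint = 0
        if len(self.hist) >= 30:
            H = np.stack(self.hist)  # (W, S, P2)
            S, P2 = self.theta.shape
            for s in range(S):
                cov = np.cov(H[:, s, :].T) + 1e-9 * np.eye(P2)
                try:
                    self.L[s] = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    pass
        self._reset_counters()


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _rhat(arr: np.ndarray) -> float:
    return float(az.rhat(np.asarray(arr)))


def fit_hierarchical(
    model,
    data: pd.DataFrame,
    priors: PriorSpec | None = None,
    mcmc: MCMCSettings | None = None,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
    shift_param: str | None = None,
    p_common: float = 0.7,
) -> PosteriorSamples:
    """Fit one model hierarchically by adaptive Metropolis-within-Gibbs.

    ``data`` is a canonical trial table (see the io module); DDM variants
    need preprocessed RTs.  With ``covariates`` (one standardized row per
    subject) the subject-level mean of ``shift_param`` becomes
    ``intercept + X @ slopes`` (the covariate extension).  Sampling is
    extended once (by default) when the R-hat gate fails; a fit that still
    fails is returned with ``converged=False`` and a warning.
    """
    spec = model if hasattr(model, "model_id") else get_model(model)
    mcmc = mcmc or MCMCSettings()
    priors = priors or PriorSpec.for_model(spec)
    if spec.task == "discounting":
        subjects, nT, arrays = _pack_discounting(data, spec.uses_rt)
    else:
        subjects, nT, arrays = _pack_twostep(data, spec.uses_rt)
    covX, cov_pidx = None, -1
    if covariates is not None:
        covX, cov_names = _prepare_covariates(covariates, subjects)
        shift_param = shift_param or _default_shift_param(spec)
        cov_pidx = spec.all_names.index(shift_param)
    else:
        cov_names = ()

    chains = [
        _Chain(spec, priors, arrays, nT, p_common,
               seed=(int(seed) * 1000003 + 61 * c + 17) % (2**31 - 1),
               covX=covX, cov_pidx=cov_pidx)
        for c in range(mcmc.chains)
    ]
    # burn-in with adaptation
    batch = 0
    for start in range(0, mcmc.burn_in, mcmc.adapt_interval):
        steps = min(mcmc.adapt_interval, mcmc.burn_in - start)
        for ch in chains:
            for _ in range(steps):
                ch.step()
            ch.adapt(batch)
        batch += 1

    def collect(n_iter):
        kept = n_iter // mcmc.thin
        P2 = 2 * len(spec.params)
        S = len(subjects)
        gm = np.empty((mcmc.chains, kept, P2))
        gs = np.empty((mcmc.chains, kept, P2))
        th = np.empty((mcmc.chains, kept, S, P2))
        sl = (np.empty((mcmc.chains, kept, covX.shape[1]))
              if covX is not None else None)
        for ci, ch in enumerate(chains):
            k = 0
            for it in range(n_iter):
                ch.step()
                if (it + 1) % mcmc.thin == 0:
                    gm[ci, k] = ch.mu
                    gs[ci, k] = ch.sig
                    th[ci, k] = ch.theta
                    if sl is not None:
                        sl[ci, k] = ch.slopes
                    k += 1
        return gm, gs, th, sl

    gm, gs, th, sl = collect(mcmc.draws)
    converged, rhat = _convergence(spec, gm, gs, th, sl, cov_names, mcmc.rhat_gate)
    ext = 0
    while not converged and ext < mcmc.max_extensions:
        ext += 1
        logger.info("R-hat gate %.3f failed (max %.3f); extending sampling (%d)",
                    mcmc.rhat_gate, max(rhat.values()), ext)
        gm, gs, th, sl = collect(mcmc.draws)
        converged, rhat = _convergence(spec, gm, gs, th, sl, cov_names, mcmc.rhat_gate)
    if not converged:
        logger.warning(
            "fit of %s flagged non-converged (max R-hat %.3f > %.3f)",
            spec.name, max(rhat.values()), mcmc.rhat_gate,
        )

    pointwise = _pointwise_loglik(spec, th, arrays, nT, p_common, mcmc.pointwise_max_draws)
    meta = dict(
        model=spec.name,
        seed=int(seed),
        fingerprint=data_fingerprint(data),
        subjects=subjects,
        n_trials=int(nT.sum()),
        p_common=p_common,
        settings=mcmc,
    )
    return PosteriorSamples(
        model=spec.name,
        param_names=spec.all_names,
        group_mean=gm,
        group_sd=gs,
        subject=th,
        pointwise_loglik=pointwise,
        rhat=rhat,
        converged=converged,
        meta=meta,
        slopes=sl,
        cov_names=tuple(cov_names),
    )


def _default_shift_param(spec: ModelSpec) -> str:
    if "s_k_log" in spec.all_names:
        return "s_k_log"
    return spec.all_names[len(spec.params)]


def _prepare_covariates(covariates: pd.DataFrame, subjects):
    cov = covariates.copy()
    if "subject" in cov.columns:
        cov = cov.set_index("subject")
    try:
        cov = cov.loc[subjects]
    except KeyError as e:
        raise ValueError(f"covariate rows do not match subjects: {e}") from None
    X = cov.to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    if np.any(np.abs(mu) > 0.2) or np.any(np.abs(sd - 1.0) > 0.3):
        logger.info("covariates do not look standardized; standardizing internally")
        sd = np.where(sd > 0, sd, 1.0)
        X = (X - mu) / sd
    return X, tuple(cov.columns)


def _convergence(spec, gm, gs, th, sl, cov_names, gate):
    rhat = {}
    for j, name in enumerate(spec.all_names):
        rhat[f"mu_{name}"] = _rhat(gm[:, :, j])
        rhat[f"sigma_{name}"] = _rhat(gs[:, :, j])
    # subject-level parameters: report the worst one
    C, K, S, P2 = th.shape
    worst = 1.0
    for s in range(S):
        for j in range(P2):
            worst = max(worst, _rhat(th[:, :, s, j]))
    rhat["subject_max"] = worst
    if sl is not None:
        for j, name in enumerate(cov_names):
            rhat[f"slope_{name}"] = _rhat(sl[:, :, j])
    finite = {k: v for k, v in rhat.items() if np.isfinite(v)}
    converged = all(v <= gate for v in finite.values())
    return converged, rhat


def _pointwise_loglik(spec, th, arrays, nT, p_common, max_draws):
    C, K, S, P2 = th.shape
    TH = th.reshape(C * K, S, P2)
    if TH.shape[0] > max_draws:
        idx = np.linspace(0, TH.shape[0] - 1, max_draws).astype(int)
        TH = TH[idx]
    offsets = np.concatenate([[0], np.cumsum(nT)])[:-1].astype(np.int64)
    out = np.empty((TH.shape[0], int(nT.sum())))
    if spec.task == "discounting":
        _pointwise_draws_disc(spec.model_id, TH, *arrays, nT, offsets, out)
    else:
        _pointwise_draws_two(spec.model_id, TH, *arrays, nT, p_common, offsets, out)
    return out


def fit_shift_covariate_model(
    model,
    data: pd.DataFrame,
    covariates: pd.DataFrame,
    priors: PriorSpec | None = None,
    mcmc: MCMCSettings | None = None,
    seed: int = 0,
    shift_param: str | None = None,
) -> PosteriorSamples:
    """Covariate extension: the subject-level mean of one shift parameter is a
    linear combination of standardized per-subject scores (slopes get
    zero-centered unit-normal priors and directional BFs in the summary)."""
    return fit_hierarchical(model, data, priors=priors, mcmc=mcmc, seed=seed,
                            covariates=covariates, shift_param=shift_param)


# ---------------------------------------------------------------------------
# WAIC / directional BF / model comparison
# ---------------------------------------------------------------------------


def compute_waic(pointwise_loglik: np.ndarray) -> WAICResult:
    """WAIC = -2 (lppd - p_waic) from a (draws, trials) log-likelihood matrix.

    ``p_waic`` is the summed pointwise posterior variance of the
    log-likelihood; lower WAIC means better expected fit.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a (draws >= 2, trials) log-likelihood matrix")
    if not np.all(np.isfinite(ll)):
        raise ValueError("log-likelihood draws must be finite")
    D = ll.shape[0]
    m = ll.max(axis=0)
    lppd_i = m + np.log(np.exp(ll - m).mean(axis=0))
    p_i = ll.var(axis=0, ddof=1)
    elpd_i = lppd_i - p_i
    pointwise = -2.0 * elpd_i
    n = ll.shape[1]
    se = math.sqrt(n * pointwise.var(ddof=1)) if n > 1 else 0.0
    return WAICResult(
        waic=float(pointwise.sum()),
        p_waic=float(p_i.sum()),
        lppd=float(lppd_i.sum()),
        se=float(se),
        pointwise=pointwise,
    )


_BANDS = [(100.0, "extreme"), (30.0, "very strong"), (10.0, "strong"),
          (3.0, "moderate"), (1.0, "anecdotal")]


def evidence_band(bf: float) -> str:
    r = bf if bf >= 1.0 else (np.inf if bf == 0.0 else 1.0 / bf)
    for cut, name in _BANDS:
        if r > cut:
            return name
    return "anecdotal"


def directional_bf(shift_draws, n_grid: int = 4096) -> DirectionalBF:
    """Directional Bayes factor of a posterior sample.

    Mass of the kernel-density estimate above 0 divided by mass below 0;
    values > 1 favor a positive shift (gambling > neutral).  If every draw
    lies on one side the ratio is reported as ``inf`` (or 0) and flagged.
    """
    x = np.asarray(shift_draws, dtype=float).reshape(-1)
    if x.size < 2:
        raise ValueError("need at least 2 draws")
    if x.std() == 0.0:
        value = np.inf if x[0] > 0 else 0.0
        return DirectionalBF(value, "extreme", "positive" if x[0] > 0 else "negative", True)
    kde = gaussian_kde(x)
    bw = kde.factor * x.std(ddof=1)
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, n_grid)
    dens = kde(grid)
    above = np.trapezoid(np.where(grid > 0, dens, 0.0), grid)
    below = np.trapezoid(np.where(grid < 0, dens, 0.0), grid)
    if below <= 0.0 or above <= 0.0:
        value = np.inf if below <= 0.0 else 0.0
        return DirectionalBF(value, "extreme",
                             "positive" if below <= 0.0 else "negative", True)
    value = above / below
    return DirectionalBF(float(value), evidence_band(value),
                         "positive" if value >= 1.0 else "negative", False)


def compare_models(fits: list[PosteriorSamples]) -> pd.DataFrame:
    """Rank fits of the same data by WAIC (ascending = best first)."""
    if len(fits) == 0:
        raise ValueError("no fits to compare")
    fps = {f.meta["fingerprint"] for f in fits}
    if len(fps) > 1:
        raise ValueError("fits were computed on different data (fingerprint mismatch)")
    res = [(f, compute_waic(f.pointwise_loglik)) for f in fits]
    res.sort(key=lambda t: t[1].waic)
    best_pw = res[0][1].pointwise
    rows = []
    for f, w in res:
        dpw = w.pointwise - best_pw
        n = dpw.size
        rows.append(
            dict(
                model=f.model,
                waic=w.waic,
                p_waic=w.p_waic,
                se=w.se,
                d_waic=w.waic - res[0][1].waic,
                d_se=math.sqrt(n * dpw.var(ddof=1)) if n > 1 else 0.0,
                converged=f.converged,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parameter-recovery harness
# ---------------------------------------------------------------------------


def run_parameter_recovery(
    model: str,
    n_subjects: int = 30,
    seed: int = 0,
    mcmc: MCMCSettings | None = None,
    group_means: dict | None = None,
    group_sds: dict | None = None,
) -> dict:
    """Simulate a cohort from known group parameters, fit it, and report
    truth vs estimate for group means plus subject-level correlations."""
    from . import synthetic
    from .discounting import preprocess_discounting_rts
    from .twostep import preprocess_twostep_rts

    spec = get_model(model)
    cohort = synthetic.CohortSpec(
        n_subjects=n_subjects,
        group_means=group_means or dict(synthetic.DEFAULT_GROUP_MEANS[model]),
        group_sds=group_sds or dict(synthetic.DEFAULT_GROUP_SDS[model]),
        seed=seed,
    )
    if spec.task == "discounting":
        design = synthetic.make_discounting_design(1, (0, 1), seed=seed + 1)
        data = synthetic.simulate_discounting_cohort(cohort, design, model)
        if spec.uses_rt:
            data = preprocess_discounting_rts(data)
    else:
        data = synthetic.simulate_twostep_cohort(cohort, model=model)
        if spec.uses_rt:
            data = preprocess_twostep_rts(data)
    truth = data.attrs["true_params"]
    fit = fit_hierarchical(model, data, mcmc=mcmc, seed=seed + 2)
    est_group = {n: float(fit.group_mean_draws(n).mean()) for n in spec.all_names}
    true_mat = np.array([truth[s] for s in fit.meta["subjects"]])
    est_mat = fit.subject_means()
    corr = {}
    for j, name in enumerate(spec.all_names):
        t = true_mat[:, j]
        e = est_mat[:, j]
        if t.std() > 0 and e.std() > 0:
            corr[name] = float(np.corrcoef(t, e)[0, 1])
        else:
            corr[name] = np.nan
    return dict(
        truth_group_means={n: cohort.group_means.get(n, 0.0) for n in spec.all_names},
        estimated_group_means=est_group,
        subject_correlation=corr,
        fit=fit,
    )
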