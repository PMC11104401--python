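"""Temporal discounting models with context-shift parameters.

A single-parameter hyperbolic model gives the subjective value of the
larger-later (LL) option on trial t,

    SV(LL_t) = A_t / (1 + exp(k + s_k * I_t) * D_t),

with the discount rate fitted in log-space and ``I_t`` a 0/1 dummy flagging
the gambling context.  The smaller-sooner (SS) option is a fixed 20 EUR
immediate reward, so SV(SS) = 20 throughout.  Four choice rules map values to
behaviour:

- ``softmax``  — logistic choice on (beta + s_beta*I) * (SV(LL) - 20);
- ``ddm0``     — Wiener first-passage likelihood with a value-free drift;
- ``ddm_lin``  — drift linear in the value difference, v = v_coeff * dSV;
- ``ddm_s``    — the linear drift passed through an odd sigmoid with
                 asymptote v_max (drift saturates for easy decisions).

Every parameter x has a companion shift s_x entering as x + s_x * I_t.
RTs are signed (LL choices positive, SS negative) and per-participant
percentile-trimmed before DDM fitting.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from numba import njit

from .wiener import _wiener_logpdf_scalar

__all__ = [
    "SS_AMOUNT",
    "subjective_value",
    "softmax_ll_probability",
    "drift_linear",
    "drift_sigmoid",
    "preprocess_discounting_rts",
    "discounting_loglik",
]

SS_AMOUNT = 20.0
TRIM_FRACTION = 0.025


def subjective_value(A, D, k_log, s_k=0.0, I=0):
    """Hyperbolic subjective value of the LL reward.

    ``A`` is the LL amount (EUR), ``D`` the delay in days, ``k_log`` the log
    discount rate and ``s_k`` its context shift (active when ``I = 1``).
    """
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("delay must be non-negative")
    k_eff = np.exp(k_log + s_k * np.asarray(I))
    out = A / (1.0 + k_eff * D)
    return out if out.ndim else float(out)


def softmax_ll_probability(sv_ll, beta, s_beta=0.0, I=0):
    """Probability of choosing LL under logistic (softmax) action selection."""
    x = (beta + s_beta * np.asarray(I)) * (np.asarray(sv_ll, dtype=float) - SS_AMOUNT)
    out = _sigmoid(x)
    return out if np.ndim(out) else float(out)


def drift_linear(sv_ll, v_coeff, s_vcoeff=0.0, I=0):
    """Trial drift as the scaled subjective value difference."""
    out = (v_coeff + s_vcoeff * np.asarray(I)) * (np.asarray(sv_ll, dtype=float) - SS_AMOUNT)
    return out if np.ndim(out) else float(out)


def drift_sigmoid(m, v_max, s_vmax=0.0, I=0):
    """Odd sigmoid squashing of an unbounded drift input.

    ``S(m) = 2 V / (1 + exp(-m)) - V`` with asymptote ``V = v_max + s_vmax*I``;
    bounded in (-V, V) and zero at ``m = 0``.
    """
    V = v_max + s_vmax * np.asarray(I)
    if np.any(np.asarray(V) <= 0):
        raise ValueError("effective drift asymptote v_max must be > 0")
    out = 2.0 * V * _sigmoid(np.asarray(m, dtype=float)) - V
    return out if np.ndim(out) else float(out)


def _sigmoid(x):
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def preprocess_discounting_rts(trials: pd.DataFrame) -> pd.DataFrame:
    """Sign and percentile-trim raw response times.

    SS-choice RTs are multiplied by -1 (``rt_signed`` column) and, per
    participant, the fastest and slowest ``floor(0.025 * n)`` trials by
    absolute RT are dropped (ties resolved by trial order).  Expects positive
    raw ``rt`` and a 0/1 ``choice`` column (1 = LL).
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    req = {"subject", "choice", "rt"}
    missing = req - set(trials.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = []
    for _, sub in trials.groupby("subject", sort=False):
        if len(sub) == 0:
            raise ValueError("empty subject data")
        sub = sub.copy()
        sign = np.where(sub["choice"].to_numpy() == 1, 1.0, -1.0)
        sub["rt_signed"] = sign * sub["rt"].to_numpy(dtype=float)
        n = len(sub)
        k = int(math.floor(TRIM_FRACTION * n))
        if k > 0:
            order = np.argsort(np.abs(sub["rt_signed"].to_numpy()), kind="stable")
            drop = np.concatenate([order[:k], order[-k:]])
            keep = np.ones(n, dtype=bool)
            keep[drop] = False
            sub = sub.iloc[keep]
        sub.attrs = {}
        out.append(sub)
    res = pd.concat(out, ignore_index=True)
    res.attrs = dict(trials.attrs)
    return res


# ---------------------------------------------------------------------------
# numba likelihood kernels (dispatch on ModelSpec.model_id)
#   0 softmax : th = [k_log, beta | shifts]
#   1 ddm0    : th = [alpha, tau, z, v | shifts]
#   2 ddm_lin : th = [k_log, alpha, tau, z, v_coeff | shifts]
#   3 ddm_s   : th = [k_log, alpha, tau, z, v_coeff, v_max | shifts]
# ---------------------------------------------------------------------------


@njit(cache=True)
def _log_sigmoid(x):
    if x >= 0.0:
        return -math.log1p(math.exp(-x))
    return x - math.log1p(math.exp(x))


@njit(cache=True)
def _disc_trial_loglik(model_id, th, A, D, i, c, rt):
    if model_id == 0:
        k = th[0] + th[2] * i
        b = th[1] + th[3] * i
        sv = A / (1.0 + math.exp(k) * D)
        x = b * (sv - 20.0)
        return _log_sigmoid(x) if c == 1 else _log_sigmoid(-x)
    if model_id == 1:
        al = th[0] + th[4] * i
        ta = th[1] + th[5] * i
        zz = th[2] + th[6] * i
        v = th[3] + th[7] * i
        if al <= 0.0 or zz <= 0.0 or zz >= 1.0 or ta < 0.0:
            return -np.inf
        return _wiener_logpdf_scalar(rt, al, ta, zz, v)
    if model_id == 2:
        k = th[0] + th[5] * i
        al = th[1] + th[6] * i
        ta = th[2] + th[7] * i
        zz = th[3] + th[8] * i
        vc = th[4] + th[9] * i
        if al <= 0.0 or zz <= 0.0 or zz >= 1.0 or ta < 0.0:
            return -np.inf
        sv = A / (1.0 + math.exp(k) * D)
        return _wiener_logpdf_scalar(rt, al, ta, zz, vc * (sv - 20.0))
    # ddm_s
    k = th[0] + th[6] * i
    al = th[1] + th[7] * i
    ta = th[2] + th[8] * i
    zz = th[3] + th[9] * i
    vc = th[4] + th[10] * i
    vm = th[5] + th[11] * i
    if al <= 0.0 or zz <= 0.0 or zz >= 1.0 or ta < 0.0 or vm <= 0.0:
        return -np.inf
    sv = A / (1.0 + math.exp(k) * D)
    m = vc * (sv - 20.0)
    if m >= 0.0:
        s = 1.0 / (1.0 + math.exp(-m))
    else:
        e = math.exp(m)
        s = e / (1.0 + e)
    return _wiener_logpdf_scalar(rt, al, ta, zz, 2.0 * vm * s - vm)


@njit(cache=True)
def _disc_pointwise(model_id, th, A, D, I, C, RT, n, out):
    for t in range(n):
        out[t] = _disc_trial_loglik(model_id, th, A[t], D[t], I[t], C[t], RT[t])


@njit(cache=True)
def _disc_loglik_sum(model_id, th, A, D, I, C, RT, n):
    s = 0.0
    for t in range(n):
        s += _disc_trial_loglik(model_id, th, A[t], D[t], I[t], C[t], RT[t])
    return s


@njit(cache=True)
def _disc_choiceprob_obs(model_id, th, A, D, I, C, RT, n, out):
    """Probability assigned to the *observed* choice on each trial.

    For DDM variants this is the closed-form absorption probability at the
    boundary implied by the observed choice (upper = LL).
    """
    for t in range(n):
        i = I[t]
        if model_id == 0:
            k = th[0] + th[2] * i
            b = th[1] + th[3] * i
            sv = A[t] / (1.0 + math.exp(k) * D[t])
            x = b * (sv - 20.0)
            p_ll = math.exp(_log_sigmoid(x))
            al = 1.0  # unused
        else:
            if model_id == 1:
                al = th[0] + th[4] * i
                zz = th[2] + th[6] * i
                v = th[3] + th[7] * i
            elif model_id == 2:
                al = th[1] + th[6] * i
                zz = th[3] + th[8] * i
                k = th[0] + th[5] * i
                sv = A[t] / (1.0 + math.exp(k) * D[t])
                v = (th[4] + th[9] * i) * (sv - 20.0)
            else:
                al = th[1] + th[7] * i
                zz = th[3] + th[9] * i
                k = th[0] + th[6] * i
                vm = th[5] + th[11] * i
                sv = A[t] / (1.0 + math.exp(k) * D[t])
                m = (th[4] + th[10] * i) * (sv - 20.0)
                if m >= 0.0:
                    s = 1.0 / (1.0 + math.exp(-m))
                else:
                    e = math.exp(m)
                    s = e / (1.0 + e)
                v = 2.0 * vm * s - vm
            if abs(v) < 1e-12:
                p_ll = zz
            else:
                p_ll = (1.0 - math.exp(-2.0 * v * al * zz)) / (1.0 - math.exp(-2.0 * v * al))
        out[t] = p_ll if C[t] == 1 else 1.0 - p_ll


def _trials_to_arrays(trials: pd.DataFrame, uses_rt: bool):
    A = trials["ll_amount"].to_numpy(dtype=float)
    D = trials["delay"].to_numpy(dtype=float)
    I = trials["context"].to_numpy(dtype=np.int64)
    C = trials["choice"].to_numpy(dtype=np.int64)
    if uses_rt:
        if "rt_signed" not in trials.columns:
            raise ValueError(
                "DDM variants need signed RTs; run preprocess_discounting_rts first"
            )
        RT = trials["rt_signed"].to_numpy(dtype=float)
    else:
        RT = np.zeros(len(trials))
    return A, D, I, C, RT


def discounting_loglik(model, params, trials: pd.DataFrame) -> np.ndarray:
    """Pointwise (per-trial) log-likelihood under one model variant.

    ``model`` is a registry name or :class:`~ctxddm.registry.ModelSpec`;
    ``params`` a ``{name: value}`` dict (missing shifts default to 0) or a
    flat vector in canonical order.
    """
    from .registry import get_model, params_to_vector

    spec = model if hasattr(model, "model_id") else get_model(model)
    if spec.task != "discounting":
        raise ValueError(f"model {spec.name!r} is not a discounting model")
    th = params if isinstance(params, np.ndarray) else params_to_vector(spec, params)
    _check_support(spec, th)
    A, D, I, C, RT = _trials_to_arrays(trials, spec.uses_rt)
    out = np.empty(len(trials))
    _disc_pointwise(spec.model_id, th, A, D, I, C, RT, len(trials), out)
    return out


def _check_support(spec, th):
    lo, hi = spec.low_high()
    P = len(spec.params)
    base = np.asarray(th[:P], dtype=float)
    eff = base + np.asarray(th[P:], dtype=float)
    for vals in (base, eff):
        bad = (vals < lo) | (vals > hi)
        if np.any(bad):
            name = spec.params[int(np.argmax(bad))]
            raise ValueError(
                f"parameter {name!r} outside support for model {spec.name!r}"
            )
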