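"""Hybrid model-free / model-based learner for the two-step task.

On each trial a first-stage (S1) choice between two actions leads, with fixed
70/30 transition probabilities, to one of two second-stage (S2) states, where
a second choice yields a reward magnitude (a Gaussian random walk, rescaled
to [0, 1]).  Model-free (MF) Q-values are updated by prediction errors at
both stages with separate learning rates eta1 and eta2 (eligibility trace
fixed to 1); model-based (MB) S1 values are recomputed each trial from the
transition structure and the current S2 values by a one-step Bellman lookahead.
Q-values of all unchosen options decay toward the reward-walk mean (0.5) with
rate eta_decay.  Choice rules:

- ``softmax_hybrid`` — S1 softmax over beta_MB*Q_MB + beta_MF*Q_MF + rho*rep(a),
  S2 softmax over beta_2 * Q_MF,S2;
- ``rlddm_lin`` / ``rlddm_s`` — per-stage Wiener first-passage likelihoods
  (z fixed at 0.5, stage-specific boundary separation and non-decision time)
  with drifts linear in MB/MF Q-value differences, optionally squashed by a
  stage-specific sigmoid with asymptote vmax;
- ``rlddm_null`` — per-stage Wiener likelihood with value-free drifts.

Every parameter x again has an additive context shift s_x (active when the
trial's context indicator is 1).  The upper DDM boundary is fixed to stimulus
1 of the stage's canonical stimulus ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .discounting import _log_sigmoid
from .wiener import _wiener_logpdf_scalar

__all__ = [
    "QState",
    "TwoStepTrial",
    "init_qstate",
    "mf_update",
    "mb_values",
    "decay_unchosen",
    "s1_choice_probability",
    "s2_choice_probability",
    "rlddm_drifts",
    "preprocess_twostep_rts",
    "twostep_loglik",
]

P_COMMON_DEFAULT = 0.7
RT_FLOOR = 0.150  # seconds
TRIM_FRACTION = 0.025


@dataclass
class QState:
    """MF values for both stages plus bookkeeping of the last choices."""

    q_mf_s1: np.ndarray = field(default_factory=lambda: np.full(2, 0.5))
    q_mf_s2: np.ndarray = field(default_factory=lambda: np.full((2, 2), 0.5))
    last_s1_action: int | None = None

    def copy(self) -> "QState":
        return QState(self.q_mf_s1.copy(), self.q_mf_s2.copy(), self.last_s1_action)


@dataclass
class TwoStepTrial:
    s1_action: int
    transition: int  # 0 common, 1 rare
    s2_state: int
    s2_action: int
    reward: float  # rescaled to [0, 1]
    context: int = 0
    rt_s1: float = np.nan
    rt_s2: float = np.nan


def init_qstate() -> QState:
    return QState()


def _get(trial, key):
    if hasattr(trial, key):
        return getattr(trial, key)
    return trial[key]


def _eff(params, name, I):
    return params.get(name, 0.0) + params.get(f"s_{name}", 0.0) * I


def mf_update(state: QState, trial, params: dict, I: int = 0) -> QState:
    """Prediction-error update of MF values after one trial.

    delta_S2 = r - Q_S2(chosen); delta_S1 uses the *pre-update* Q_S2 of the
    visited state's chosen action; the S1 update is
    Q_S1 += eta1 * delta_S1 + eta2 * delta_S2 (eligibility trace of 1).
    """
    e1 = _eff(params, "eta1", I)
    e2 = _eff(params, "eta2", I)
    if not (0.0 <= e1 <= 1.0 and 0.0 <= e2 <= 1.0):
        raise ValueError("effective learning rates must lie in [0, 1]")
    a1 = int(_get(trial, "s1_action"))
    s2 = int(_get(trial, "s2_state"))
    a2 = int(_get(trial, "s2_action"))
    r = float(_get(trial, "reward"))
    out = state.copy()
    d2 = r - out.q_mf_s2[s2, a2]
    d1 = out.q_mf_s2[s2, a2] - out.q_mf_s1[a1]
    out.q_mf_s2[s2, a2] += e2 * d2
    out.q_mf_s1[a1] += e1 * d1 + e2 * d2
    out.last_s1_action = a1
    return out


def mb_values(state: QState, p_common: float = P_COMMON_DEFAULT) -> np.ndarray:
    """Bellman S1 values: transition-weighted maxima of the S2 MF values.

    S1 action j preferentially (p_common) reaches S2 state j.
    """
    m = state.q_mf_s2.max(axis=1)  # best attainable value per S2 state
    return np.array(
        [
            p_common * m[0] + (1.0 - p_common) * m[1],
            p_common * m[1] + (1.0 - p_common) * m[0],
        ]
    )


def decay_unchosen(state: QState, trial, params: dict, I: int = 0) -> QState:
    """Relax every unchosen Q toward the walk mean 0.5.

    ``Q <- Q * rate + (1 - rate) * 0.5`` with rate = eta_decay + s*I; applies
    to the unchosen S1 action and all S2 entries except the visited state's
    chosen action (stages k in {1, 21, 22}).
    """
    ed = _eff(params, "eta_decay", I)
    if not 0.0 <= ed <= 1.0:
        raise ValueError("effective decay rate must lie in [0, 1]")
    a1 = int(_get(trial, "s1_action"))
    s2 = int(_get(trial, "s2_state"))
    a2 = int(_get(trial, "s2_action"))
    out = state.copy()
    for a in range(2):
        if a != a1:
            out.q_mf_s1[a] = out.q_mf_s1[a] * ed + (1.0 - ed) * 0.5
    for s in range(2):
        for a in range(2):
            if not (s == s2 and a == a2):
                out.q_mf_s2[s, a] = out.q_mf_s2[s, a] * ed + (1.0 - ed) * 0.5
    return out


def s1_choice_probability(
    state: QState, params: dict, I: int = 0, prev_action: int | None = None,
    p_common: float = P_COMMON_DEFAULT,
) -> np.ndarray:
    """Softmax over the MB/MF mixture with a perseveration bonus."""
    bmb = _eff(params, "beta_MB", I)
    bmf = _eff(params, "beta_MF", I)
    rho = _eff(params, "rho", I)
    qmb = mb_values(state, p_common)
    w = bmb * qmb + bmf * state.q_mf_s1
    if prev_action is not None:
        w[int(prev_action)] += rho
    x = w[1] - w[0]
    p1 = math.exp(_log_sigmoid(x))
    return np.array([1.0 - p1, p1])


def s2_choice_probability(state: QState, params: dict, I: int = 0, s2_state: int = 0) -> np.ndarray:
    """Softmax over the visited S2 state's two MF values."""
    b2 = _eff(params, "beta_2", I)
    q = state.q_mf_s2[int(s2_state)]
    p1 = math.exp(_log_sigmoid(b2 * (q[1] - q[0])))
    return np.array([1.0 - p1, p1])


def rlddm_drifts(
    state: QState,
    params: dict,
    I: int = 0,
    prev_action: int | None = None,
    s2_state: int = 0,
    variant: str = "lin",
    p_common: float = P_COMMON_DEFAULT,
) -> tuple[float, float]:
    """Stage-wise drift rates toward the upper (stimulus-1) boundary."""
    vmf = _eff(params, "vcoeff_mf", I)
    vmb = _eff(params, "vcoeff_mb", I)
    vs2 = _eff(params, "vcoeff_s2", I)
    rho = _eff(params, "rho", I)
    qmb = mb_values(state, p_common)
    rep = 0.0
    if prev_action is not None:
        rep = rho if int(prev_action) == 1 else -rho
    v1 = vmb * (qmb[1] - qmb[0]) + vmf * (state.q_mf_s1[1] - state.q_mf_s1[0]) + rep
    q = state.q_mf_s2[int(s2_state)]
    v2 = vs2 * (q[1] - q[0])
    if variant == "s":
        vm1 = _eff(params, "vmax_s1", I)
        vm2 = _eff(params, "vmax_s2", I)
        if vm1 <= 0.0 or vm2 <= 0.0:
            raise ValueError("effective vmax must be > 0")
        v1 = 2.0 * vm1 / (1.0 + math.exp(-v1)) - vm1
        v2 = 2.0 * vm2 / (1.0 + math.exp(-v2)) - vm2
    elif variant != "lin":
        raise ValueError("variant must be 'lin' or 's'")
    return float(v1), float(v2)


def preprocess_twostep_rts(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-stage RT filters as likelihood masks.

    Per participant and stage, the fastest and slowest ``floor(0.025 * n)``
    trials plus any RT below 150 ms are excluded from the Wiener likelihood
    (columns ``use_rt_s1`` / ``use_rt_s2``).  Trials are kept in the table:
    the learner is sequential, so excluded-RT trials still drive value
    updates; only their RT likelihood contribution is dropped.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    req = {"subject", "rt_s1", "rt_s2"}
    missing = req - set(trials.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = trials.copy()
    for stage in ("s1", "s2"):
        col = f"rt_{stage}"
        use = np.ones(len(out), dtype=np.int64)
        for _, idx in out.groupby("subject", sort=False).indices.items():
            rts = out[col].to_numpy(dtype=float)[idx]
            n = len(idx)
            k = int(math.floor(TRIM_FRACTION * n))
            if k > 0:
                order = np.argsort(rts, kind="stable")
                use[idx[order[:k]]] = 0
                use[idx[order[-k:]]] = 0
            use[idx[rts < RT_FLOOR]] = 0
        out[f"use_rt_{stage}"] = use
    return out


# ---------------------------------------------------------------------------
# numba kernels (dispatch on ModelSpec.model_id)
#   0 softmax_hybrid : [eta1, eta2, eta_decay, beta_MB, beta_MF, beta_2, rho]
#   1 rlddm_lin      : [eta1, eta2, eta_decay, alpha_s1, alpha_s2, tau_s1,
#                       tau_s2, vcoeff_mf, vcoeff_mb, vcoeff_s2, rho]
#   2 rlddm_s        : rlddm_lin + [vmax_s1, vmax_s2]
#   3 rlddm_null     : [alpha_s1, alpha_s2, tau_s1, tau_s2, v_s1, v_s2]
# (each followed by its shifts; context-effective value = base + shift * I)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _squash(m, vm):
    if m >= 0.0:
        s = 1.0 / (1.0 + math.exp(-m))
    else:
        e = math.exp(m)
        s = e / (1.0 + e)
    return 2.0 * vm * s - vm


@njit(cache=True)
def _two_pointwise(model_id, th, a1, s2, a2, r, I, rt1, rt2, u1, u2, reset, n, p_common, out):
    P = th.size // 2
    q1 = np.empty(2)
    q2 = np.empty((2, 2))
    prev = -1
    for t in range(n):
        if reset[t] == 1:
            q1[0] = 0.5
            q1[1] = 0.5
            q2[0, 0] = 0.5
            q2[0, 1] = 0.5
            q2[1, 0] = 0.5
            q2[1, 1] = 0.5
            prev = -1
        i = I[t]
        ll = 0.0
        m0 = q2[0, 0] if q2[0, 0] > q2[0, 1] else q2[0, 1]
        m1 = q2[1, 0] if q2[1, 0] > q2[1, 1] else q2[1, 1]
        qmb0 = p_common * m0 + (1.0 - p_common) * m1
        qmb1 = p_common * m1 + (1.0 - p_common) * m0
        st = s2[t]
        if model_id == 0:
            bmb = th[3] + th[P + 3] * i
            bmf = th[4] + th[P + 4] * i
            b2 = th[5] + th[P + 5] * i
            rho = th[6] + th[P + 6] * i
            w0 = bmb * qmb0 + bmf * q1[0] + (rho if prev == 0 else 0.0)
            w1 = bmb * qmb1 + bmf * q1[1] + (rho if prev == 1 else 0.0)
            x = w1 - w0
            ll += _log_sigmoid(x) if a1[t] == 1 else _log_sigmoid(-x)
            y = b2 * (q2[st, 1] - q2[st, 0])
            ll += _log_sigmoid(y) if a2[t] == 1 else _log_sigmoid(-y)
        elif model_id == 3:
            al1 = th[0] + th[P] * i
            al2 = th[1] + th[P + 1] * i
            ta1 = th[2] + th[P + 2] * i
            ta2 = th[3] + th[P + 3] * i
            v1 = th[4] + th[P + 4] * i
            v2 = th[5] + th[P + 5] * i
            if al1 <= 0.0 or al2 <= 0.0 or ta1 < 0.0 or ta2 < 0.0:
                ll = -np.inf
            else:
                if u1[t] == 1:
                    srt = rt1[t] if a1[t] == 1 else -rt1[t]
                    ll += _wiener_logpdf_scalar(srt, al1, ta1, 0.5, v1)
                if u2[t] == 1:
                    srt = rt2[t] if a2[t] == 1 else -rt2[t]
                    ll += _wiener_logpdf_scalar(srt, al2, ta2, 0.5, v2)
        else:
            al1 = th[3] + th[P + 3] * i
            al2 = th[4] + th[P + 4] * i
            ta1 = th[5] + th[P + 5] * i
            ta2 = th[6] + th[P + 6] * i
            vmf = th[7] + th[P + 7] * i
            vmb = th[8] + th[P + 8] * i
            vs2 = th[9] + th[P + 9] * i
            rho = th[10] + th[P + 10] * i
            if al1 <= 0.0 or al2 <= 0.0 or ta1 < 0.0 or ta2 < 0.0:
                ll = -np.inf
            else:
                rep = 0.0
                if prev == 1:
                    rep = rho
                elif prev == 0:
                    rep = -rho
                v1 = vmb * (qmb1 - qmb0) + vmf * (q1[1] - q1[0]) + rep
                v2 = vs2 * (q2[st, 1] - q2[st, 0])
                if model_id == 2:
                    vm1 = th[11] + th[P + 11] * i
                    vm2 = th[12] + th[P + 12] * i
                    if vm1 <= 0.0 or vm2 <= 0.0:
                        ll = -np.inf
                    else:
                        v1 = _squash(v1, vm1)
                        v2 = _squash(v2, vm2)
                if np.isfinite(ll):
                    if u1[t] == 1:
                        srt = rt1[t] if a1[t] == 1 else -rt1[t]
                        ll += _wiener_logpdf_scalar(srt, al1, ta1, 0.5, v1)
                    if u2[t] == 1:
                        srt = rt2[t] if a2[t] == 1 else -rt2[t]
                        ll += _wiener_logpdf_scalar(srt, al2, ta2, 0.5, v2)
        # learning updates (value-free null model skips them)
        if model_id != 3:
            e1 = th[0] + th[P] * i
            e2 = th[1] + th[P + 1] * i
            ed = th[2] + th[P + 2] * i
            d2 = r[t] - q2[st, a2[t]]
            d1 = q2[st, a2[t]] - q1[a1[t]]
            q2[st, a2[t]] += e2 * d2
            q1[a1[t]] += e1 * d1 + e2 * d2
            for a in range(2):
                if a != a1[t]:
                    q1[a] = q1[a] * ed + (1.0 - ed) * 0.5
            for s in range(2):
                for a in range(2):
                    if not (s == st and a == a2[t]):
                        q2[s, a] = q2[s, a] * ed + (1.0 - ed) * 0.5
        prev = a1[t]
        out[t] = ll


@njit(cache=True)
def _two_loglik_sum(model_id, th, a1, s2, a2, r, I, rt1, rt2, u1, u2, reset, n, p_common):
    out = np.empty(n)
    _two_pointwise(model_id, th, a1, s2, a2, r, I, rt1, rt2, u1, u2, reset, n, p_common, out)
    s = 0.0
    for t in range(n):
        s += out[t]
    return s


@njit(cache=True)
def _two_choiceprob_obs(model_id, th, a1, s2, a2, r, I, reset, n, p_common, out1, out2):
    """Probability assigned to the observed S1/S2 choices, replaying the
    learner on the observed sequence (DDMs: closed-form absorption, z=0.5)."""
    P = th.size // 2
    q1 = np.empty(2)
    q2 = np.empty((2, 2))
    prev = -1
    for t in range(n):
        if reset[t] == 1:
            q1[0] = 0.5
            q1[1] = 0.5
            q2[0, 0] = 0.5
            q2[0, 1] = 0.5
            q2[1, 0] = 0.5
            q2[1, 1] = 0.5
            prev = -1
        i = I[t]
        m0 = q2[0, 0] if q2[0, 0] > q2[0, 1] else q2[0, 1]
        m1 = q2[1, 0] if q2[1, 0] > q2[1, 1] else q2[1, 1]
        qmb0 = p_common * m0 + (1.0 - p_common) * m1
        qmb1 = p_common * m1 + (1.0 - p_common) * m0
        st = s2[t]
        if model_id == 0:
            bmb = th[3] + th[P + 3] * i
            bmf = th[4] + th[P + 4] * i
            b2 = th[5] + th[P + 5] * i
            rho = th[6] + th[P + 6] * i
            w0 = bmb * qmb0 + bmf * q1[0] + (rho if prev == 0 else 0.0)
            w1 = bmb * qmb1 + bmf * q1[1] + (rho if prev == 1 else 0.0)
            p1 = math.exp(_log_sigmoid(w1 - w0))
            p2 = math.exp(_log_sigmoid((b2 * (q2[st, 1] - q2[st, 0]))))
        else:
            if model_id == 3:
                al1 = th[0] + th[P] * i
                al2 = th[1] + th[P + 1] * i
                v1 = th[4] + th[P + 4] * i
                v2 = th[5] + th[P + 5] * i
            else:
                al1 = th[3] + th[P + 3] * i
                al2 = th[4] + th[P + 4] * i
                vmf = th[7] + th[P + 7] * i
                vmb = th[8] + th[P + 8] * i
                vs2 = th[9] + th[P + 9] * i
                rho = th[10] + th[P + 10] * i
                rep = 0.0
                if prev == 1:
                    rep = rho
                elif prev == 0:
                    rep = -rho
                v1 = vmb * (qmb1 - qmb0) + vmf * (q1[1] - q1[0]) + rep
                v2 = vs2 * (q2[st, 1] - q2[st, 0])
                if model_id == 2:
                    v1 = _squash(v1, th[11] + th[P + 11] * i)
                    v2 = _squash(v2, th[12] + th[P + 12] * i)
            if abs(v1) < 1e-12:
                p1 = 0.5
            else:
                p1 = (1.0 - math.exp(-v1 * al1)) / (1.0 - math.exp(-2.0 * v1 * al1))
            if abs(v2) < 1e-12:
                p2 = 0.5
            else:
                p2 = (1.0 - math.exp(-v2 * al2)) / (1.0 - math.exp(-2.0 * v2 * al2))
        out1[t] = p1 if a1[t] == 1 else 1.0 - p1
        out2[t] = p2 if a2[t] == 1 else 1.0 - p2
        if model_id != 3:
            e1 = th[0] + th[P] * i
            e2 = th[1] + th[P + 1] * i
            ed = th[2] + th[P + 2] * i
            d2 = r[t] - q2[st, a2[t]]
            d1 = q2[st, a2[t]] - q1[a1[t]]
            q2[st, a2[t]] += e2 * d2
            q1[a1[t]] += e1 * d1 + e2 * d2
            for a in range(2):
                if a != a1[t]:
                    q1[a] = q1[a] * ed + (1.0 - ed) * 0.5
            for s in range(2):
                for a in range(2):
                    if not (s == st and a == a2[t]):
                        q2[s, a] = q2[s, a] * ed + (1.0 - ed) * 0.5
        prev = a1[t]


def _session_resets(sub: pd.DataFrame) -> np.ndarray:
    """1 at the first trial of each (context-)session within a subject block."""
    if "session" in sub.columns:
        key = sub["session"].to_numpy()
    else:
        key = sub["context"].to_numpy()
    reset = np.zeros(len(sub), dtype=np.int64)
    reset[0] = 1
    reset[1:][key[1:] != key[:-1]] = 1
    return reset


def _twostep_arrays(sub: pd.DataFrame, uses_rt: bool):
    a1 = sub["s1_choice"].to_numpy(dtype=np.int64)
    s2 = sub["s2_state"].to_numpy(dtype=np.int64)
    a2 = sub["s2_choice"].to_numpy(dtype=np.int64)
    r = sub["reward"].to_numpy(dtype=float)
    I = sub["context"].to_numpy(dtype=np.int64)
    if r.size and (r.min() < 0 or r.max() > 1.0 + 1e-9):
        raise ValueError("rewards must be rescaled to [0, 1]")
    n = len(sub)
    if uses_rt:
        if "use_rt_s1" not in sub.columns:
            raise ValueError(
                "RLDDM variants need RT masks; run preprocess_twostep_rts first"
            )
        rt1 = sub["rt_s1"].to_numpy(dtype=float)
        rt2 = sub["rt_s2"].to_numpy(dtype=float)
        u1 = sub["use_rt_s1"].to_numpy(dtype=np.int64)
        u2 = sub["use_rt_s2"].to_numpy(dtype=np.int64)
    else:
        rt1 = np.zeros(n)
        rt2 = np.zeros(n)
        u1 = np.zeros(n, dtype=np.int64)
        u2 = np.zeros(n, dtype=np.int64)
    return a1, s2, a2, r, I, rt1, rt2, u1, u2, _session_resets(sub)


def twostep_loglik(
    model, params, trials: pd.DataFrame, p_common: float = P_COMMON_DEFAULT
) -> np.ndarray:
    """Pointwise per-trial log-likelihood (both stage contributions summed).

    Trials must be in chronological order within each subject; Q-values reset
    at each (subject, context) session boundary.
    """
    from .registry import get_model, params_to_vector

    spec = model if hasattr(model, "model_id") else get_model(model)
    if spec.task != "twostep":
        raise ValueError(f"model {spec.name!r} is not a two-step model")
    th = params if isinstance(params, np.ndarray) else params_to_vector(spec, params)
    from .discounting import _check_support

    _check_support(spec, th)
    out = np.empty(len(trials))
    for _, idx in trials.groupby("subject", sort=False).indices.items():
        sub = trials.iloc[idx]
        arrs = _twostep_arrays(sub, spec.uses_rt)
        buf = np.empty(len(sub))
        _two_pointwise(spec.model_id, th, *arrs, len(sub), p_common, buf)
        out[idx] = buf
    return out
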