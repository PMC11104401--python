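"""Task designs, reward walks and simulated cohorts.

Emulates the study conditions of the two tasks: an intertemporal-choice task
with a fixed 20 EUR smaller-sooner reward, larger-later rewards built as
printed multiplier sets times 20, delays in days, and two counterbalanced
task versions; and a two-step task with 70/30 transitions and reward
magnitudes following Gaussian random walks (SD 2.5, reflecting at 0 and 100),
where version-2 walks are the version-1 walks reversed.  Cohorts of subjects
are simulated from any generative model in the registry by drawing subject
parameters from (truncated) Gaussian group distributions; DDM variants sample
response times by first-passage simulation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .registry import ModelSpec, get_model
from .wiener import DEFAULT_DT, _sample_wiener_one, sample_wiener

__all__ = [
    "MULTIPLIERS",
    "DELAYS",
    "DiscountingDesign",
    "TransitionStructure",
    "CohortSpec",
    "DEFAULT_GROUP_MEANS",
    "DEFAULT_GROUP_SDS",
    "make_discounting_design",
    "make_reward_walks",
    "simulate_transition",
    "simulate_discounting_cohort",
    "simulate_twostep_cohort",
    "sample_wiener",
]

logger = logging.getLogger("ctxddm")

# printed LL multiplier and delay sets of the two task versions
MULTIPLIERS = {
    1: (1.05, 1.055, 1.15, 1.25, 1.35, 1.45, 1.55, 1.65,
        1.85, 2.05, 2.25, 2.55, 2.85, 3.05, 3.45, 3.85),
    2: (1.025, 1.08, 1.2, 1.20, 1.33, 1.47, 1.5, 1.70,
        1.83, 2.07, 2.3, 2.5, 2.80, 3.10, 3.5, 3.80),
}
DELAYS = {1: (1, 7, 13, 31, 58, 122), 2: (2, 6, 15, 29, 62, 118)}

SS_AMOUNT = 20.0
WALK_SD = 2.5
WALK_BOUNDS = (0.0, 100.0)
N_WALKS = 4
DEFAULT_TWOSTEP_TRIALS = 300
DEFAULT_DISCOUNTING_TRIALS = 140


@dataclass(frozen=True)
class TransitionStructure:
    """S1 action -> preferred S2 state map with common-transition probability."""

    p_common: float = 0.7
    mapping: tuple[int, int] = (0, 1)

    def __post_init__(self):
        if not 0.0 <= self.p_common <= 1.0:
            raise ValueError("p_common must be a probability")
        if self.mapping[0] == self.mapping[1]:
            raise ValueError("the two S1 actions must prefer different S2 states")


@dataclass
class DiscountingDesign:
    version: int
    trials: pd.DataFrame  # ss_amount, ll_amount, delay, context, ll_on_left

    def __len__(self):
        return len(self.trials)


@dataclass
class CohortSpec:
    n_subjects: int
    group_means: dict
    group_sds: dict
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(v < 0 for v in self.group_sds.values()):
            raise ValueError("group_sds must be non-negative")


def make_discounting_design(
    version: int,
    context_order=(0, 1),
    n_trials: int = DEFAULT_DISCOUNTING_TRIALS,
    seed: int = 0,
) -> DiscountingDesign:
    """Build a per-subject intertemporal-choice design.

    One block (session) per entry of ``context_order``; the task version
    alternates across sessions starting from ``version`` (counterbalancing).
    Each block is the full 16 x 6 multiplier-by-delay cross, shuffled; if
    ``n_trials`` exceeds the 96-cell cross, extra trials are resampled
    uniformly from the cross.  Screen side of the LL option is randomized and
    recorded (``ll_on_left``).
    """
    if version not in (1, 2):
        raise ValueError("version must be 1 or 2")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    blocks = []
    v = version
    for sess, ctx in enumerate(context_order):
        if ctx not in (0, 1):
            raise ValueError("context entries must be 0 or 1")
        mult = np.array(MULTIPLIERS[v], dtype=float)
        dely = np.array(DELAYS[v], dtype=float)
        mm, dd = np.meshgrid(mult, dely, indexing="ij")
        cells = np.column_stack([mm.ravel(), dd.ravel()])
        n_cross = len(cells)
        if n_trials <= n_cross:
            pick = rng.permutation(n_cross)[:n_trials]
        else:
            logger.info(
                "requested %d trials exceeds the %d-cell cross; "
                "resampling extra trials uniformly",
                n_trials,
                n_cross,
            )
            extra = rng.integers(0, n_cross, size=n_trials - n_cross)
            pick = rng.permutation(np.concatenate([np.arange(n_cross), extra]))
        chosen = cells[pick]
        blocks.append(
            pd.DataFrame(
                {
                    "session": sess,
                    "trial": np.arange(n_trials),
                    "context": ctx,
                    "version": v,
                    "ss_amount": SS_AMOUNT,
                    "ll_amount": SS_AMOUNT * chosen[:, 0],
                    "delay": chosen[:, 1],
                    "ll_on_left": rng.integers(0, 2, size=n_trials),
                }
            )
        )
        v = 2 if v == 1 else 1
    return DiscountingDesign(version=version, trials=pd.concat(blocks, ignore_index=True))


def make_reward_walks(
    n_trials: int = DEFAULT_TWOSTEP_TRIALS,
    step_sd: float = WALK_SD,
    bounds=WALK_BOUNDS,
    seed: int = 0,
    reverse: bool = False,
    n_series: int = N_WALKS,
) -> np.ndarray:
    """Gaussian random walks with reflecting boundaries.

    Returns an ``(n_series, n_trials)`` array in points.  Reflection applies
    ``value <- 2 * bound - value`` when a step crosses a bound.  With
    ``reverse=True`` the series are time-reversed (the second task version).
    """
    lo, hi = float(bounds[0]), float(bounds[1])
    if not lo < hi:
        raise ValueError("invalid bounds: lower must be < upper")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if step_sd < 0:
        raise ValueError("step_sd must be >= 0")
    rng = np.random.default_rng(seed)
    start = rng.uniform(lo + 0.25 * (hi - lo), hi - 0.25 * (hi - lo), size=n_series)
    walks = np.empty((n_series, n_trials))
    for s in range(n_series):
        x = start[s]
        for t in range(n_trials):
            walks[s, t] = x
            x = x + rng.normal(0.0, step_sd)
            while x < lo or x > hi:  # reflect (twice if the step is huge)
                if x < lo:
                    x = 2.0 * lo - x
                if x > hi:
                    x = 2.0 * hi - x
    if reverse:
        walks = walks[:, ::-1].copy()
    return walks


def simulate_transition(s1_action: int, structure: TransitionStructure, seed: int):
    """Sample the S2 state reached from one S1 action.

    Returns ``(s2_state, transition_type)`` with type ``"common"`` or
    ``"rare"``.
    """
    if s1_action not in (0, 1):
        raise ValueError("s1_action must be 0 or 1")
    rng = np.random.default_rng(seed)
    preferred = structure.mapping[s1_action]
    other = structure.mapping[1 - s1_action]
    if rng.random() < structure.p_common:
        return preferred, "common"
    return other, "rare"


# paper-informed group-level defaults (posterior means where printed; plausible
# values for quantities the study does not print)
DEFAULT_GROUP_MEANS = {
    "softmax": {"k_log": -4.0, "beta": 0.3, "s_k_log": 0.77, "s_beta": 0.025},
    "ddm0": {
        "alpha": 1.6, "tau": 0.45, "z": 0.45, "v": 0.2,
        "s_alpha": 0.10, "s_tau": -0.05, "s_z": 0.02, "s_v": 0.0,
    },
    "ddm_lin": {},
    "ddm_s": {},
    "softmax_hybrid": {
        "eta1": 0.35, "eta2": 0.40, "eta_decay": 0.65,
        "beta_MB": 4.0, "beta_MF": 3.0, "beta_2": 6.0, "rho": 0.8,
        "s_eta1": 0.44, "s_eta2": 0.40, "s_eta_decay": 0.0,
        "s_beta_MB": 1.08, "s_beta_MF": -1.14, "s_beta_2": -0.44, "s_rho": 0.04,
    },
    "rlddm_lin": {},
    "rlddm_s": {},
    "rlddm_null": {
        "alpha_s1": 1.4, "alpha_s2": 1.4, "tau_s1": 0.3, "tau_s2": 0.3,
        "v_s1": 0.5, "v_s2": 0.8,
    },
}
DEFAULT_GROUP_MEANS["ddm_lin"] = {
    "k_log": -4.0, "alpha": 1.6, "tau": 0.45, "z": 0.45, "v_coeff": 0.1,
    "s_k_log": 0.40, "s_alpha": 0.10, "s_tau": -0.05, "s_z": 0.02, "s_v_coeff": -0.012,
}
DEFAULT_GROUP_MEANS["ddm_s"] = {
    "k_log": -4.0, "alpha": 1.6, "tau": 0.45, "z": 0.45,
    "v_coeff": 0.25, "v_max": 2.0,
    "s_k_log": 0.40, "s_alpha": 0.10, "s_tau": -0.05, "s_z": 0.02,
    "s_v_coeff": -0.012, "s_v_max": 0.33,
}
_RLDDM_BASE = {
    "eta1": 0.35, "eta2": 0.40, "eta_decay": 0.65,
    "alpha_s1": 1.4, "alpha_s2": 1.4, "tau_s1": 0.3, "tau_s2": 0.3,
    "vcoeff_mf": 1.5, "vcoeff_mb": 2.5, "vcoeff_s2": 4.0, "rho": 0.3,
    "s_eta1": 0.0801, "s_eta2": 0.280, "s_eta_decay": 0.0,
    "s_alpha_s1": -0.002, "s_alpha_s2": 0.0149,
    "s_tau_s1": 0.001, "s_tau_s2": 0.001,
    "s_vcoeff_mf": -0.93, "s_vcoeff_mb": 4.01, "s_vcoeff_s2": -0.64,
    "s_rho": 0.05,
}
DEFAULT_GROUP_MEANS["rlddm_lin"] = dict(_RLDDM_BASE)
DEFAULT_GROUP_MEANS["rlddm_s"] = dict(
    _RLDDM_BASE,
    vmax_s1=2.5, vmax_s2=3.5, s_vmax_s1=-0.19, s_vmax_s2=0.41,
)

DEFAULT_GROUP_SDS = {
    "softmax": {"k_log": 1.0, "beta": 0.15, "s_k_log": 0.3, "s_beta": 0.05},
    "ddm0": {
        "alpha": 0.3, "tau": 0.1, "z": 0.05, "v": 0.3,
        "s_alpha": 0.1, "s_tau": 0.05, "s_z": 0.03, "s_v": 0.1,
    },
    "ddm_lin": {
        "k_log": 1.0, "alpha": 0.3, "tau": 0.1, "z": 0.05, "v_coeff": 0.04,
        "s_k_log": 0.2, "s_alpha": 0.1, "s_tau": 0.05, "s_z": 0.03, "s_v_coeff": 0.02,
    },
    "ddm_s": {
        "k_log": 1.0, "alpha": 0.3, "tau": 0.1, "z": 0.05,
        "v_coeff": 0.1, "v_max": 0.5,
        "s_k_log": 0.2, "s_alpha": 0.1, "s_tau": 0.05, "s_z": 0.03,
        "s_v_coeff": 0.05, "s_v_max": 0.2,
    },
    "softmax_hybrid": {
        "eta1": 0.12, "eta2": 0.12, "eta_decay": 0.15,
        "beta_MB": 1.5, "beta_MF": 1.2, "beta_2": 2.0, "rho": 0.5,
        "s_eta1": 0.1, "s_eta2": 0.12, "s_eta_decay": 0.05,
        "s_beta_MB": 0.8, "s_beta_MF": 0.6, "s_beta_2": 0.8, "s_rho": 0.1,
    },
    "rlddm_null": {
        "alpha_s1": 0.25, "alpha_s2": 0.25, "tau_s1": 0.08, "tau_s2": 0.08,
        "v_s1": 0.3, "v_s2": 0.3,
    },
}
_RLDDM_SDS = {
    "eta1": 0.12, "eta2": 0.12, "eta_decay": 0.15,
    "alpha_s1": 0.25, "alpha_s2": 0.25, "tau_s1": 0.08, "tau_s2": 0.08,
    "vcoeff_mf": 0.5, "vcoeff_mb": 0.8, "vcoeff_s2": 1.2, "rho": 0.2,
    "s_eta1": 0.1, "s_eta2": 0.12, "s_eta_decay": 0.05,
    "s_alpha_s1": 0.08, "s_alpha_s2": 0.08, "s_tau_s1": 0.03, "s_tau_s2": 0.03,
    "s_vcoeff_mf": 0.3, "s_vcoeff_mb": 0.8, "s_vcoeff_s2": 0.3, "s_rho": 0.1,
}
DEFAULT_GROUP_SDS["rlddm_lin"] = dict(_RLDDM_SDS)
DEFAULT_GROUP_SDS["rlddm_s"] = dict(
    _RLDDM_SDS, vmax_s1=0.6, vmax_s2=0.8, s_vmax_s1=0.2, s_vmax_s2=0.2
)


def default_cohort_spec(model: str, n_subjects: int, seed: int = 0) -> CohortSpec:
    """Cohort spec at the package's default group-level distributions."""
    return CohortSpec(
        n_subjects=n_subjects,
        group_means=dict(DEFAULT_GROUP_MEANS[model]),
        group_sds=dict(DEFAULT_GROUP_SDS[model]),
        seed=seed,
    )


def _draw_subject_params(spec: ModelSpec, cohort: CohortSpec, rng) -> np.ndarray:
    """Truncated-Gaussian subject draws honouring the support constraints."""
    lo, hi = spec.low_high()
    P = len(spec.params)
    out = np.empty((cohort.n_subjects, 2 * P))
    for s in range(cohort.n_subjects):
        for _ in range(10000):
            vec = np.empty(2 * P)
            for j, name in enumerate(spec.all_names):
                m = cohort.group_means.get(name, 0.0)
                sd = cohort.group_sds.get(name, 0.0)
                vec[j] = rng.normal(m, sd) if sd > 0 else m
            base, shift = vec[:P], vec[P:]
            if np.all(base >= lo) and np.all(base <= hi) and np.all(
                base + shift >= lo
            ) and np.all(base + shift <= hi):
                out[s] = vec
                break
        else:
            raise ValueError(
                "could not draw parameters inside the model support; "
                "check group means/SDs"
            )
    return out


def simulate_discounting_cohort(
    spec: CohortSpec,
    design: DiscountingDesign,
    model: str = "softmax",
    dt: float = DEFAULT_DT,
) -> pd.DataFrame:
    """Simulate an intertemporal-choice cohort from one generative model.

    Every subject sees the same design (contexts/sessions as built).  Softmax
    subjects contribute choices only; DDM subjects contribute signed-RT
    choices sampled by Euler first-passage simulation.  Returns a long table
    with the true subject parameters attached (``true_<name>`` columns are
    stored in ``df.attrs["true_params"]``).
    """
    mspec = get_model(model)
    if mspec.task != "discounting":
        raise ValueError(f"{model!r} is not a discounting model")
    rng = np.random.default_rng(spec.seed)
    theta = _draw_subject_params(mspec, spec, rng)
    rows = []
    base = design.trials
    for s in range(spec.n_subjects):
        th = theta[s]
        sub = base.copy()
        sub.insert(0, "subject", s)
        A = sub["ll_amount"].to_numpy()
        D = sub["delay"].to_numpy()
        I = sub["context"].to_numpy()
        if mspec.name == "softmax":
            k = th[0] + th[2] * I
            b = th[1] + th[3] * I
            sv = A / (1.0 + np.exp(k) * D)
            p_ll = 1.0 / (1.0 + np.exp(-b * (sv - SS_AMOUNT)))
            sub["choice"] = (rng.random(len(sub)) < p_ll).astype(int)
        else:
            al, ta, zz, v = _disc_trial_ddm_params(mspec, th, A, D, I)
            seed_s = int(rng.integers(0, 2**31 - 1))
            srt = _simulate_rts(al, ta, zz, v, dt, seed_s)
            sub["choice"] = (srt > 0).astype(int)
            sub["rt"] = np.abs(srt)
        rows.append(sub)
    df = pd.concat(rows, ignore_index=True)
    df.attrs["true_params"] = {s: tuple(theta[s]) for s in range(spec.n_subjects)}
    df.attrs["model"] = mspec.name
    return df


def _disc_trial_ddm_params(mspec: ModelSpec, th, A, D, I):
    """Trial-wise effective DDM parameters for a discounting DDM variant."""
    P = len(mspec.params)
    get = dict(zip(mspec.params, range(P)))

    def eff(name):
        j = get[name]
        return th[j] + th[j + P] * I

    if mspec.name == "ddm0":
        v = eff("v") * np.ones(len(A))
    else:
        sv = A / (1.0 + np.exp(eff("k_log")) * D)
        m = eff("v_coeff") * (sv - SS_AMOUNT)
        if mspec.name == "ddm_s":
            vm = eff("v_max")
            v = 2.0 * vm / (1.0 + np.exp(-m)) - vm
        else:
            v = m
    ones = np.ones(len(A))
    return eff("alpha") * ones, eff("tau") * ones, eff("z") * ones, v


@njit(cache=True)
def _simulate_rts(alphas, taus, zs, vs, dt, seed):
    np.random.seed(seed)
    n = alphas.size
    out = np.empty(n)
    for t in range(n):
        out[t] = _sample_wiener_one(alphas[t], taus[t], zs[t], vs[t], dt, 30.0, True)
    return out


@njit(cache=True)
def _simulate_twostep_subject(model_id, th, walks, I, reset, p_common, dt, seed,
                              a1o, tro, s2o, a2o, ro, rt1o, rt2o):
    """Generative rollout of one subject; walks is (4, n) in [0, 1] laid out
    as (state, action) = (0,0),(0,1),(1,0),(1,1); arrays are filled in place."""
    np.random.seed(seed)
    n = I.size
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
        # stage 1 choice
        if model_id == 0:
            bmb = th[3] + th[P + 3] * i
            bmf = th[4] + th[P + 4] * i
            rho = th[6] + th[P + 6] * i
            w0 = bmb * qmb0 + bmf * q1[0] + (rho if prev == 0 else 0.0)
            w1 = bmb * qmb1 + bmf * q1[1] + (rho if prev == 1 else 0.0)
            p1 = 1.0 / (1.0 + math.exp(-(w1 - w0)))
            a1 = 1 if np.random.rand() < p1 else 0
            rt1 = np.nan
        else:
            if model_id == 3:
                al1 = th[0] + th[P] * i
                ta1 = th[2] + th[P + 2] * i
                v1 = th[4] + th[P + 4] * i
            else:
                al1 = th[3] + th[P + 3] * i
                ta1 = th[5] + th[P + 5] * i
                vmf = th[7] + th[P + 7] * i
                vmb = th[8] + th[P + 8] * i
                rho = th[10] + th[P + 10] * i
                rep = 0.0
                if prev == 1:
                    rep = rho
                elif prev == 0:
                    rep = -rho
                v1 = vmb * (qmb1 - qmb0) + vmf * (q1[1] - q1[0]) + rep
                if model_id == 2:
                    v1 = _squash_nb(v1, th[11] + th[P + 11] * i)
            x = _sample_wiener_one(al1, ta1, 0.5, v1, dt, 30.0, True)
            a1 = 1 if x > 0 else 0
            rt1 = abs(x)
        # transition
        common = np.random.rand() < p_common
        s2 = a1 if common else 1 - a1
        # stage 2 choice
        if model_id == 0:
            b2 = th[5] + th[P + 5] * i
            y = b2 * (q2[s2, 1] - q2[s2, 0])
            p2 = 1.0 / (1.0 + math.exp(-y))
            a2 = 1 if np.random.rand() < p2 else 0
            rt2 = np.nan
        else:
            if model_id == 3:
                al2 = th[1] + th[P + 1] * i
                ta2 = th[3] + th[P + 3] * i
                v2 = th[5] + th[P + 5] * i
            else:
                al2 = th[4] + th[P + 4] * i
                ta2 = th[6] + th[P + 6] * i
                v2 = (th[9] + th[P + 9] * i) * (q2[s2, 1] - q2[s2, 0])
                if model_id == 2:
                    v2 = _squash_nb(v2, th[12] + th[P + 12] * i)
            x = _sample_wiener_one(al2, ta2, 0.5, v2, dt, 30.0, True)
            a2 = 1 if x > 0 else 0
            rt2 = abs(x)
        r = walks[2 * s2 + a2, t]
        # learning updates
        if model_id != 3:
            e1 = th[0] + th[P] * i
            e2 = th[1] + th[P + 1] * i
            ed = th[2] + th[P + 2] * i
            d2 = r - q2[s2, a2]
            d1 = q2[s2, a2] - q1[a1]
            q2[s2, a2] += e2 * d2
            q1[a1] += e1 * d1 + e2 * d2
            for a in range(2):
                if a != a1:
                    q1[a] = q1[a] * ed + (1.0 - ed) * 0.5
            for s in range(2):
                for a in range(2):
                    if not (s == s2 and a == a2):
                        q2[s, a] = q2[s, a] * ed + (1.0 - ed) * 0.5
        prev = a1
        a1o[t] = a1
        tro[t] = 0 if common else 1
        s2o[t] = s2
        a2o[t] = a2
        ro[t] = r
        rt1o[t] = rt1
        rt2o[t] = rt2


@njit(cache=True)
def _squash_nb(m, vm):
    if m >= 0.0:
        s = 1.0 / (1.0 + math.exp(-m))
    else:
        e = math.exp(m)
        s = e / (1.0 + e)
    return 2.0 * vm * s - vm


def simulate_twostep_cohort(
    spec: CohortSpec,
    walks: np.ndarray | None = None,
    structure: TransitionStructure = TransitionStructure(),
    model: str = "softmax_hybrid",
    context_order=(0, 1),
    dt: float = DEFAULT_DT,
) -> pd.DataFrame:
    """Simulate a two-step cohort from one generative model.

    One session per entry of ``context_order``; session 2 uses the session-1
    walks reversed (paired-version mode).  ``walks`` is in points (0-100) and
    defaults to fresh walks from the cohort seed; rewards in the output are
    rescaled to [0, 1].  The four current reward magnitudes are carried along
    (``w00``..``w11``, rescaled) for reward-difference diagnostics.
    """
    mspec = get_model(model)
    if mspec.task != "twostep":
        raise ValueError(f"{model!r} is not a two-step model")
    rng = np.random.default_rng(spec.seed)
    if walks is None:
        walks = make_reward_walks(seed=int(rng.integers(0, 2**31 - 1)))
    if walks.min() < WALK_BOUNDS[0] or walks.max() > WALK_BOUNDS[1]:
        raise ValueError("walks must lie within the 0-100 point bounds")
    theta = _draw_subject_params(mspec, spec, rng)
    n = walks.shape[1]
    sessions = []
    for sess, ctx in enumerate(context_order):
        w = walks if sess % 2 == 0 else walks[:, ::-1]
        sessions.append((sess, ctx, (w / WALK_BOUNDS[1]).copy()))
    rows = []
    for s in range(spec.n_subjects):
        th = theta[s]
        for sess, ctx, w in sessions:
            I = np.full(n, ctx, dtype=np.int64)
            reset = np.zeros(n, dtype=np.int64)
            reset[0] = 1
            a1 = np.empty(n, dtype=np.int64)
            tr = np.empty(n, dtype=np.int64)
            s2 = np.empty(n, dtype=np.int64)
            a2 = np.empty(n, dtype=np.int64)
            r = np.empty(n)
            rt1 = np.empty(n)
            rt2 = np.empty(n)
            seed_s = int(rng.integers(0, 2**31 - 1))
            _simulate_twostep_subject(
                mspec.model_id, th, w, I, reset, structure.p_common, dt, seed_s,
                a1, tr, s2, a2, r, rt1, rt2,
            )
            sub = pd.DataFrame(
                {
                    "subject": s,
                    "session": sess,
                    "trial": np.arange(n),
                    "context": ctx,
                    "s1_choice": a1,
                    "transition": tr,
                    "s2_state": s2,
                    "s2_choice": a2,
                    "reward": r,
                    "rt_s1": rt1,
                    "rt_s2": rt2,
                    "w00": w[0],
                    "w01": w[1],
                    "w10": w[2],
                    "w11": w[3],
                }
            )
            rows.append(sub)
    df = pd.concat(rows, ignore_index=True)
    if mspec.name == "softmax_hybrid":
        df = df.drop(columns=["rt_s1", "rt_s2"])
    df.attrs["true_params"] = {s: tuple(theta[s]) for s in range(spec.n_subjects)}
    df.attrs["model"] = mspec.name
    return df
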