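"""Model registry: canonical parameter orderings, supports and task bindings.

Every model exposes a flat subject-level parameter vector laid out as
``[base_0, ..., base_{P-1}, s_0, ..., s_{P-1}]`` where ``s_p`` is the additive
context shift of ``base_p`` (active when the context indicator ``I = 1``).
Both the baseline value and the shifted value ``base + s`` must lie inside the
declared support.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ModelSpec:
    """Binding of a model name to its likelihood kernel and parameters."""

    name: str
    task: str  # "discounting" | "twostep"
    model_id: int  # dispatch code used by the numba kernels
    params: tuple[str, ...]  # baseline parameter names, canonical order
    uses_rt: bool  # True for DDM variants (joint choice/RT likelihood)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return 2 * len(self.params)

    @property
    def all_names(self) -> tuple[str, ...]:
        return self.params + tuple(f"s_{p}" for p in self.params)

    def low_high(self):
        import numpy as np

        lo = np.array([self.bounds[p][0] for p in self.params])
        hi = np.array([self.bounds[p][1] for p in self.params])
        return lo, hi


# supports double as the uniform prior ranges for baseline group means
_DISC_BOUNDS = {
    "k_log": (-8.0, 1.0),
    "beta": (0.0, 20.0),
    "alpha": (0.05, 5.0),
    "tau": (0.05, 2.0),
    "z": (0.05, 0.95),
    "v": (-10.0, 10.0),
    "v_coeff": (-2.0, 2.0),
    "v_max": (0.05, 10.0),
}

_TWO_BOUNDS = {
    "eta1": (0.0, 1.0),
    "eta2": (0.0, 1.0),
    "eta_decay": (0.0, 1.0),
    "beta_MB": (0.0, 20.0),
    "beta_MF": (0.0, 20.0),
    "beta_2": (0.0, 20.0),
    "rho": (-5.0, 5.0),
    "alpha_s1": (0.05, 5.0),
    "alpha_s2": (0.05, 5.0),
    "tau_s1": (0.05, 2.0),
    "tau_s2": (0.05, 2.0),
    "v_s1": (-10.0, 10.0),
    "v_s2": (-10.0, 10.0),
    "vcoeff_mf": (-20.0, 20.0),
    "vcoeff_mb": (-20.0, 20.0),
    "vcoeff_s2": (-20.0, 20.0),
    "vmax_s1": (0.05, 10.0),
    "vmax_s2": (0.05, 10.0),
}


def _spec(name, task, model_id, params, uses_rt, table):
    return ModelSpec(
        name=name,
        task=task,
        model_id=model_id,
        params=tuple(params),
        uses_rt=uses_rt,
        bounds={p: table[p] for p in params},
    )


MODEL_REGISTRY: dict[str, ModelSpec] = {
    s.name: s
    for s in [
        _spec("softmax", "discounting", 0, ["k_log", "beta"], False, _DISC_BOUNDS),
        _spec("ddm0", "discounting", 1, ["alpha", "tau", "z", "v"], True, _DISC_BOUNDS),
        _spec(
            "ddm_lin",
            "discounting",
            2,
            ["k_log", "alpha", "tau", "z", "v_coeff"],
            True,
            _DISC_BOUNDS,
        ),
        _spec(
            "ddm_s",
            "discounting",
            3,
            ["k_log", "alpha", "tau", "z", "v_coeff", "v_max"],
            True,
            _DISC_BOUNDS,
        ),
        _spec(
            "softmax_hybrid",
            "twostep",
            0,
            ["eta1", "eta2", "eta_decay", "beta_MB", "beta_MF", "beta_2", "rho"],
            False,
            _TWO_BOUNDS,
        ),
        _spec(
            "rlddm_lin",
            "twostep",
            1,
            [
                "eta1",
                "eta2",
                "eta_decay",
                "alpha_s1",
                "alpha_s2",
                "tau_s1",
                "tau_s2",
                "vcoeff_mf",
                "vcoeff_mb",
                "vcoeff_s2",
                "rho",
            ],
            True,
            _TWO_BOUNDS,
        ),
        _spec(
            "rlddm_s",
            "twostep",
            2,
            [
                "eta1",
                "eta2",
                "eta_decay",
                "alpha_s1",
                "alpha_s2",
                "tau_s1",
                "tau_s2",
                "vcoeff_mf",
                "vcoeff_mb",
                "vcoeff_s2",
                "rho",
                "vmax_s1",
                "vmax_s2",
            ],
            True,
            _TWO_BOUNDS,
        ),
        _spec(
            "rlddm_null",
            "twostep",
            3,
            ["alpha_s1", "alpha_s2", "tau_s1", "tau_s2", "v_s1", "v_s2"],
            True,
            _TWO_BOUNDS,
        ),
    ]
}


def get_model(name: str) -> ModelSpec:
    """Look up a model by registry name; raises ``KeyError`` with options."""
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}"
        ) from None


def params_to_vector(spec: ModelSpec, params: dict) -> "np.ndarray":
    """Flatten a ``{name: value}`` dict into the canonical vector.

    Missing shift entries default to 0 (no context effect); missing baseline
    entries are an error.
    """
    import numpy as np

    vec = np.empty(spec.n_params)
    for i, p in enumerate(spec.params):
        if p not in params:
            raise KeyError(f"missing baseline parameter {p!r} for model {spec.name!r}")
        vec[i] = params[p]
        vec[i + len(spec.params)] = params.get(f"s_{p}", 0.0)
    return vec


def vector_to_params(spec: ModelSpec, vec) -> dict:
    return {n: float(v) for n, v in zip(spec.all_names, vec)}
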