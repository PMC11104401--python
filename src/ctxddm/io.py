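"""Readers/writers, run configuration, logging and the end-to-end pipeline.

Canonical on-disk format is CSV with one row per trial.  Mandatory columns:

- discounting: ``subject, context, ll_amount, delay, choice`` (+ ``rt`` in
  seconds for DDM variants; ``choice`` is 1 = larger-later, 0 = smaller-sooner)
- twostep: ``subject, context, trial, s1_choice, transition, s2_state,
  s2_choice, reward`` (+ ``rt_s1, rt_s2`` for RLDDM variants; ``transition``
  is 0 = common, 1 = rare; rewards rescaled to [0, 1])

Arbitrary source column names are mapped onto this schema with a
``schema_map``; a JSON sidecar records generating parameters and seeds for
simulated data, and every pipeline run writes a manifest with SHA-256 hashes
of its inputs and outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("ctxddm")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

__all__ = [
    "read_choice_data",
    "write_choice_data",
    "RunConfig",
    "load_run_config",
    "run_pipeline",
    "PipelineError",
]

MANDATORY = {
    "discounting": ["subject", "context", "ll_amount", "delay", "choice"],
    "twostep": [
        "subject", "context", "trial", "s1_choice", "transition",
        "s2_state", "s2_choice", "reward",
    ],
}
_CHOICE_CODES = {"ll": 1, "ss": 0, "1": 1, "0": 0, "1.0": 1, "0.0": 0}
_TRANSITION_CODES = {"common": 0, "rare": 1, "0": 0, "1": 1, "0.0": 0, "1.0": 1}


def read_choice_data(
    path,
    task: str,
    schema_map: dict | None = None,
    rt_unit: str = "s",
    reward_unit: str = "auto",
) -> pd.DataFrame:
    """Read and validate a trial table from delimited text.

    ``schema_map`` maps source column names to canonical field names.  RT
    columns declared in milliseconds (``rt_unit="ms"``) are divided by 1000;
    two-step rewards in points (``reward_unit="points"``, or auto-detected
    when the maximum exceeds 1) are rescaled to [0, 1].  Unparseable rows are
    reported with their file line numbers.
    """
    if task not in MANDATORY:
        raise ValueError("task must be 'discounting' or 'twostep'")
    df = pd.read_csv(path, sep=None, engine="python")
    if schema_map:
        df = df.rename(columns=schema_map)
    missing = [c for c in MANDATORY[task] if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s) {missing} in {path}")

    bad_lines: list[int] = []

    def coerce(col, codes=None, dtype=float):
        vals = []
        for i, v in enumerate(df[col]):
            try:
                if codes is not None:
                    key = str(v).strip().lower()
                    vals.append(codes[key] if key in codes else int(float(v)))
                else:
                    vals.append(dtype(v))
            except (ValueError, KeyError, TypeError):
                bad_lines.append(i + 2)  # header is line 1
                vals.append(np.nan)
        df[col] = vals

    coerce("context", codes={"neutral": 0, "gambling": 1, "0": 0, "1": 1})
    if task == "discounting":
        coerce("choice", codes=_CHOICE_CODES)
        coerce("ll_amount")
        coerce("delay")
    else:
        coerce("transition", codes=_TRANSITION_CODES)
        for c in ("s1_choice", "s2_state", "s2_choice"):
            coerce(c, codes={"0": 0, "1": 1, "2": 1})
        coerce("reward")
    if bad_lines:
        raise ValueError(f"unparseable rows in {path} at line(s) {sorted(set(bad_lines))[:20]}")
    if not set(df["context"].unique()) <= {0, 1}:
        raise ValueError("context must be coded 0 (neutral) / 1 (gambling)")

    rt_cols = [c for c in ("rt", "rt_s1", "rt_s2") if c in df.columns]
    if rt_unit == "ms":
        for c in rt_cols:
            df[c] = df[c].astype(float) / 1000.0
    elif rt_unit != "s":
        raise ValueError("rt_unit must be 's' or 'ms'")
    if task == "twostep":
        r = df["reward"].astype(float)
        if reward_unit == "points" or (reward_unit == "auto" and r.max() > 1.0 + 1e-9):
            logger.info("rescaling rewards from points (0-100) to [0, 1]")
            df["reward"] = r / 100.0
    return df


def write_choice_data(df: pd.DataFrame, path, params: dict | None = None,
                      seed: int | None = None) -> Path:
    """Write a trial table as CSV plus a JSON sidecar with provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    sidecar = {
        "columns": list(df.columns),
        "n_rows": int(len(df)),
        "seed": seed,
        "params": _jsonable(params) if params else None,
        "model": df.attrs.get("model"),
    }
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as f:
        json.dump(sidecar, f, indent=1, default=str)
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class RunConfig:
    """Full description of one pipeline run (YAML-loadable)."""

    task: str
    model: str
    seed: int
    outdir: str
    data: str | None = None  # path to a trial CSV, or None to simulate
    schema_map: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)  # n_subjects, group overrides
    mcmc: dict = field(default_factory=dict)
    priors: str | None = None  # optional YAML overriding default priors
    n_sims_ppc: int = 50

    def __post_init__(self):
        from .registry import MODEL_REGISTRY

        if self.model not in MODEL_REGISTRY:
            raise ValueError(
                f"unknown model {self.model!r}; available: {sorted(MODEL_REGISTRY)}"
            )
        if self.task not in ("discounting", "twostep"):
            raise ValueError("task must be 'discounting' or 'twostep'")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def load_run_config(path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f)
    return RunConfig(**raw)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """simulate/load -> preprocess -> fit -> WAIC/BF -> PPC, with a manifest.

    Returns the artifact directory.  Any stage failure raises
    :class:`PipelineError` naming the stage; artifacts written before the
    failure are left in place.
    """
    from . import diagnostics, inference, synthetic
    from .discounting import preprocess_discounting_rts
    from .registry import get_model
    from .twostep import preprocess_twostep_rts

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    spec = get_model(config.model)
    manifest: dict = {"config": dataclasses.asdict(config), "outputs": {}}
    import importlib.metadata

    for pkg in ("numpy", "scipy", "pandas", "numba", "arviz", "statsmodels"):
        manifest.setdefault("versions", {})[pkg] = importlib.metadata.version(pkg)

    stage = "simulate"
    try:
        if config.data:
            data = read_choice_data(config.data, config.task, config.schema_map or None)
        else:
            sim = dict(config.simulate)
            n_subjects = int(sim.pop("n_subjects", 20))
            cohort = synthetic.CohortSpec(
                n_subjects=n_subjects,
                group_means={**synthetic.DEFAULT_GROUP_MEANS[config.model],
                             **sim.pop("group_means", {})},
                group_sds={**synthetic.DEFAULT_GROUP_SDS[config.model],
                           **sim.pop("group_sds", {})},
                seed=config.seed,
            )
            if config.task == "discounting":
                design = synthetic.make_discounting_design(1, (0, 1), seed=config.seed)
                data = synthetic.simulate_discounting_cohort(cohort, design, config.model)
            else:
                data = synthetic.simulate_twostep_cohort(cohort, model=config.model)
        logger.info("stage simulate/load done: %d trials", len(data))

        stage = "preprocess"
        if spec.uses_rt:
            if config.task == "discounting":
                data = preprocess_discounting_rts(data)
            else:
                data = preprocess_twostep_rts(data)
        data_path = write_choice_data(data, out / "data.csv", seed=config.seed)
        logger.info("stage preprocess done: %d trials retained", len(data))

        stage = "fit"
        mcmc = inference.MCMCSettings(**config.mcmc) if config.mcmc else inference.MCMCSettings()
        prior_cfg = None
        if config.priors:
            with open(config.priors) as f:
                prior_cfg = yaml.safe_load(f)
        priors = inference.PriorSpec.for_model(spec, prior_cfg)
        fit = inference.fit_hierarchical(spec, data, priors=priors, mcmc=mcmc,
                                         seed=config.seed)
        summary = fit.summary()
        summary.to_csv(out / "summary.csv", index=False)
        logger.info("stage fit done: converged=%s", fit.converged)

        stage = "waic"
        waic = inference.compute_waic(fit.pointwise_loglik)
        with open(out / "waic.json", "w") as f:
            json.dump({"waic": waic.waic, "p_waic": waic.p_waic, "se": waic.se,
                       "converged": fit.converged, "rhat_max": max(fit.rhat.values())},
                      f, indent=1)

        stage = "ppc"
        if spec.uses_rt:
            if config.task == "discounting":
                ppc = diagnostics.ppc_discounting(fit, data, n_sims=config.n_sims_ppc,
                                                  seed=config.seed)
            else:
                ppc = diagnostics.ppc_twostep(fit, data, n_sims=config.n_sims_ppc,
                                              seed=config.seed)
            ppc.conflict_bin_means.to_csv(out / "ppc_bins.csv", index=False)
            if ppc.choice_accuracy is not None:
                ppc.choice_accuracy.to_csv(out / "choice_accuracy.csv", index=False)
        else:
            acc = diagnostics.choice_accuracy(fit, data)
            acc.to_csv(out / "choice_accuracy.csv", index=False)
        logger.info("stage ppc done")
    except Exception as e:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(stage, e) from e

    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    manifest["fingerprint"] = fit.meta["fingerprint"]
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1, default=str)
    return out
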