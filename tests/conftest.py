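import numpy as np
import pytest

from ctxddm import synthetic
from ctxddm.inference import PosteriorSamples, data_fingerprint
from ctxddm.registry import get_model, params_to_vector


@pytest.fixture(scope="session")
def discounting_design():
    return synthetic.make_discounting_design(1, (0, 1), 140, seed=101)


def make_fixed_fit(model, trials, theta_by_subject, seed=0, n_draws=40, jitter=1e-3):
    """A PosteriorSamples stand-in whose draws concentrate on known subject
    parameters (synthetic posterior; used to exercise PPC machinery without
    an MCMC run)."""
    spec = get_model(model)
    subjects = list(dict.fromkeys(trials["subject"]))
    rng = np.random.default_rng(seed)
    S, P2 = len(subjects), spec.n_params
    th = np.empty((2, n_draws, S, P2))
    for si, s in enumerate(subjects):
        v = np.asarray(theta_by_subject[s], dtype=float)
        th[:, :, si, :] = v + jitter * rng.standard_normal((2, n_draws, P2))
    gm = th.mean(axis=2)
    return PosteriorSamples(
        model=spec.name,
        param_names=spec.all_names,
        group_mean=gm,
        group_sd=np.full_like(gm, jitter),
        subject=th,
        pointwise_loglik=np.zeros((4, len(trials))),
        rhat={},
        converged=True,
        meta=dict(model=spec.name, seed=seed, fingerprint=data_fingerprint(trials),
                  subjects=subjects, n_trials=len(trials), p_common=0.7),
    )


def cohort_with_params(model, n_subjects, seed, **overrides):
    """Cohort spec from the package defaults with selected entries replaced."""
    spec = synthetic.default_cohort_spec(model, n_subjects, seed)
    for k, v in overrides.items():
        if k.endswith("_sd"):
            spec.group_sds[k[:-3]] = v
        else:
            spec.group_means[k] = v
    return spec
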