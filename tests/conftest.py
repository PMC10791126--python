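"""Shared fixtures: small synthetic datasets and fitted posteriors.

Everything is generated programmatically with fixed seeds; the
module-scoped fits are reused across tests to keep the suite fast.
"""

import numpy as np
import pytest

from empabayes import censored_model as cm
from empabayes import synthetic_data as sd


@pytest.fixture(scope="session")
def small_empathy_data():
    cfg = sd.StudyConfig(
        n_control=10,
        n_experimental=10,
        ratings_per_cell=4,
        fixed_effects={"intercept": 45.0, "intensity": 27.86},
        seed=11,
    )
    return sd.generate_empathy_ratings(cfg)


@pytest.fixture(scope="session")
def empathy_fit(small_empathy_data):
    spec = cm.empathy_model_spec()
    return cm.fit_posterior(
        small_empathy_data,
        spec,
        n_chains=2,
        n_warmup=400,
        n_draws=500,
        seed=21,
        check_rhat=False,
    )


def make_posterior_draws(
    re_sd=(8.0, 2.0, 5.0, 2.5),
    corr=None,
    n_draws=2000,
    n_subjects=30,
    seed=0,
):
    """Hand-built PosteriorDraws with known variance components."""
    rng = np.random.default_rng(seed)
    terms = ["intercept", "session", "intensity", "session:intensity"]
    q = len(terms)
    if corr is None:
        corr = np.eye(q)
    sd_arr = np.tile(np.asarray(re_sd, float), (1, n_draws, 1))
    corr_arr = np.tile(corr, (1, n_draws, 1, 1))
    L = np.linalg.cholesky(corr) * np.asarray(re_sd)[:, None]
    b = np.einsum("dsq,kq->dsk", rng.standard_normal((n_draws, n_subjects, q)), L)[None]
    return cm.PosteriorDraws(
        fixed_terms=["intercept", "intensity"],
        random_terms=terms,
        subjects=[f"s{i:03d}" for i in range(n_subjects)],
        beta=rng.standard_normal((1, n_draws, 2)),
        b=b,
        re_sd=sd_arr,
        re_corr=corr_arr,
        sigma=np.abs(rng.standard_normal((1, n_draws, n_subjects))) + 5.0,
        priors=cm.PriorSpec(),
    )
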