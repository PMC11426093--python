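"""Shared fixtures: small synthetic surveys and a reusable posterior fit."""

from __future__ import annotations

import numpy as np
import pytest

from cooccupy.inference import MCMCConfig, fit
from cooccupy.synthetic import default_survey_config, simulate_histories


@pytest.fixture(scope="session")
def small_sim():
    """Paper-like synthetic survey at reduced size (fast latent path)."""
    cfg = default_survey_config(seed=42, n_sites=80)
    hist_a, hist_b, dm, truth = simulate_histories(cfg)
    return {
        "hist_a": hist_a,
        "hist_b": hist_b["roe_deer"],
        "dm": dm,
        "truth": truth,
        "cfg": cfg,
    }


@pytest.fixture(scope="session")
def h2_fit(small_sim):
    """One H2 posterior fit on the small survey, shared across tests."""
    return fit(
        (small_sim["hist_a"], small_sim["hist_b"]),
        small_sim["dm"],
        "H2",
        MCMCConfig.quick(seed=3),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_fake_fit(hyp_id="H2", draws=None, loglik=None, signature="shared", seed=1):
    """A PosteriorFit with hand-chosen draws/log-likelihoods, for testing
    post-processing independent of the sampler."""
    from cooccupy.inference import MCMCConfig, PosteriorFit
    from cooccupy.model import HYPOTHESES

    hyp = HYPOTHESES[hyp_id]
    if draws is None:
        draws = np.zeros((1, 20, hyp.n_coef))
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 2:
        draws = draws[None, :, :]
    if loglik is None:
        loglik = np.zeros(draws.shape[:2] + (5,))
    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim == 2:
        loglik = loglik[None, :, :]
    return PosteriorFit(
        hypothesis=hyp,
        coef_names=hyp.coef_names(),
        draws=draws,
        rhat=np.ones(hyp.n_coef),
        loglik=loglik,
        dm=None,
        config=MCMCConfig(seed=seed, n_iter=20, n_burnin=0, thin=1, n_chains=1),
        accept_rates={},
        data_signature=signature,
    )
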