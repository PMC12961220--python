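"""Shared fixtures: small synthetic domains, surveys and fitted models.

Everything is generated programmatically with fixed seeds; expensive fits
are session-scoped so the evaluation/prediction tests reuse them.
"""

from __future__ import annotations

import numpy as np
import pytest

import soilspde as sp


@pytest.fixture(scope="session")
def small_domain() -> sp.SyntheticDomain:
    return sp.SyntheticDomain(
        width_km=400.0, height_km=300.0, n_states_x=2, n_states_y=2,
        resolution_km=10.0,
    )


@pytest.fixture(scope="session")
def small_boundary(small_domain):
    boundary, states = sp.make_synthetic_boundary(small_domain)
    return boundary, states


def make_modeling_table(domain, n_sites, truth, seed, family="lognormal",
                        covariates=None):
    """Simulate, clean and standardize a survey; returns (table, record, truth)."""
    tab, truth = sp.simulate_survey(
        domain, n_sites, truth, family=family, seed=seed, covariates=covariates
    )
    clean = sp.clean_survey(tab)
    names = [c for c in sp.synthetic_data.COVARIATE_NAMES if c in clean.columns]
    if names:
        scaled, record = sp.standardize_covariates(clean, names)
        for c in names:
            clean[c] = scaled[c]
    else:
        record = None
    return clean, record, truth


@pytest.fixture(scope="session")
def toy_data(small_domain):
    truth = sp.SyntheticTruth(
        beta0=2.0, beta=[0.4], range_true=150.0, sigma_true=0.5,
        sigma_state=0.1, sigma_obs=0.4, seed=3,
    )
    clean, record, truth = make_modeling_table(small_domain, 100, truth, seed=3)
    return clean, record, truth


@pytest.fixture(scope="session")
def toy_mesh(toy_data, small_boundary):
    clean, _, _ = toy_data
    boundary, _ = small_boundary
    pts = clean[["x_km", "y_km"]].to_numpy()
    return sp.build_mesh(pts, boundary, sp.coarse_mesh_params(pts))


@pytest.fixture(scope="session")
def toy_fit(toy_data, toy_mesh):
    clean, _, _ = toy_data
    spec = sp.ModelSpec(covariates=["som"])
    return sp.fit(spec, clean, toy_mesh, seed=5)


@pytest.fixture(scope="session")
def iid_data():
    """Non-spatial lognormal data for closed-form comparisons."""
    rng = np.random.default_rng(42)
    n = 120
    x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    eta = 1.5 + 0.6 * x
    y = np.exp(eta + 0.4 * rng.standard_normal(n))
    import pandas as pd

    return pd.DataFrame(
        {"conc": y, "som": x, "x_km": rng.uniform(0, 100, n),
         "y_km": rng.uniform(0, 100, n), "state_id": "s0"}
    )
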