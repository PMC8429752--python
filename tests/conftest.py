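"""Shared fixtures: one seeded lab experiment, fitted model and toy grid.

Session-scoped so the expensive pieces (nonlinear fits, grid synthesis)
are built once and reused read-only across test modules.
"""

import numpy as np
import pytest

import coldrange as cr


@pytest.fixture(scope="session")
def lab_regimes():
    return cr.make_regimes(10, seed=11)


@pytest.fixture(scope="session")
def lab_observations(lab_regimes):
    return cr.simulate_survival_experiment(lab_regimes, seed=11)


@pytest.fixture(scope="session")
def lab_model(lab_observations):
    return cr.fit_survival_model(
        lab_observations, cr.ModelSpec("LTDD", "exponential"), seed=0
    )


@pytest.fixture(scope="session")
def toy_grid():
    return cr.simulate_climate_grid(
        n_lat=8, n_lon=5, year_start=2000, year_end=2010, seed=5
    )


@pytest.fixture(scope="session")
def toy_host(toy_grid):
    return cr.simulate_host_mask(toy_grid, seed=5)


@pytest.fixture(scope="session")
def annotated_records(toy_grid, lab_model):
    records = cr.simulate_resistance_records(
        400, grid=toy_grid, survival_model=lab_model, seed=17
    )
    effects = cr.compute_effect_sizes(records)
    return cr.annotate_sites(effects, toy_grid, lab_model)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
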