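"""Shared fixtures: the expensive EF1-R luminescence pipeline is fitted once
per session and reused by the unit and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

import lanthafit as lf

#: the session-wide scenario seed, fixed once for reproducibility
SEED = 1


@pytest.fixture(scope="session")
def ef1r_scenario():
    data, truth = lf.generate_trlfs_scenario("EF1-R", seed=SEED)
    return data, truth


@pytest.fixture(scope="session")
def ef1r_fit(ef1r_scenario):
    data, _ = ef1r_scenario
    return lf.fit_parafac(data, 3, init_seed=SEED, n_restarts=20)


@pytest.fixture(scope="session")
def ef1r_calib(ef1r_scenario, ef1r_fit):
    data, _ = ef1r_scenario
    return lf.calibrate_concentrations(ef1r_fit, data.compositions)


@pytest.fixture(scope="session")
def ef1r_binding(ef1r_scenario, ef1r_calib):
    data, _ = ef1r_scenario
    return lf.fit_binding_constants(ef1r_calib, data.compositions,
                                    refine_with=data)


@pytest.fixture(scope="session")
def ef1r_mc(ef1r_scenario, ef1r_fit, ef1r_calib, ef1r_binding):
    data, _ = ef1r_scenario
    return lf.mc_trlfs_pipeline(data, ef1r_fit, ef1r_calib, ef1r_binding,
                                n_runs=100, seed=SEED)


@pytest.fixture(scope="session")
def ef1r_noiseless():
    data, truth = lf.generate_trlfs_scenario("EF1-R", seed=SEED, noise=0.0)
    return data, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
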