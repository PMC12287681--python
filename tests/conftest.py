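import numpy as np
import pandas as pd
import pytest

from fluxphen import drivers as drv
from fluxphen import synthetic as sy


@pytest.fixture(scope="session")
def scenario():
    """Default 26-year subalpine scenario, fixed seed."""
    return sy.SyntheticScenario(n_years=26, seed=7)


@pytest.fixture(scope="session")
def met(scenario):
    return sy.generate_met(scenario)


@pytest.fixture(scope="session")
def daily(scenario, met):
    return sy.generate_daily_nee(scenario, met)


@pytest.fixture(scope="session")
def noisefree_run():
    """Three noise-free years: exact seasonal structure, known phenology."""
    sc = sy.SyntheticScenario(n_years=3, seed=1)
    for var in sc.variables.values():
        var.noise_sd = 0.0
    sc.nee_noise_sd = 0.0
    met = sy.generate_met(sc)
    daily = sy.generate_daily_nee(sc, met)
    return sc, met, daily


@pytest.fixture(scope="session")
def features(met):
    return drv.build_features(met)


@pytest.fixture(scope="session")
def fitted_model(features, daily):
    return drv.train_gbm(features, daily["nee"], seed=1)


@pytest.fixture(scope="session")
def attributions(fitted_model, features):
    return drv.compute_attributions(fitted_model, features)
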