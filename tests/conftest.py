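import numpy as np
import pytest

from airdcm import ModelConfig, em_fit, loso_crossval, make_scenario
from airdcm.synthetic import make_worked_micro_example


@pytest.fixture(scope="session")
def micro():
    """Fixed tiny heterotopic instance (q=2, 3 stations, T=4)."""
    return make_worked_micro_example()


@pytest.fixture(scope="session")
def scenario120():
    """Default-size synthetic scenario, one season of daily data."""
    return make_scenario(T=120, seed=7)


@pytest.fixture(scope="session")
def fit120(scenario120):
    """EM fit of the default model (z + one LCM component) on scenario120."""
    config = ModelConfig(p=3, include_u=False, include_lcm=True, c=1)
    return em_fit(scenario120.obs, scenario120.covariates, config,
                  tol=1e-5, max_iter=60)


@pytest.fixture(scope="session")
def loso120(fit120):
    return loso_crossval(fit120.obs, fit120.covariates, fit120.psi,
                         init_state_cov=fit120.init_state_cov)
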