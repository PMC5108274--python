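import numpy as np
import pytest

from ssmtrack import synthetic_data as sd
from ssmtrack.mcmc_engine import SamplerConfig, fit_model
from ssmtrack.movement_model import PriorConfig


@pytest.fixture(scope="session")
def tiny_haulout_dataset():
    spec = sd.preset("weddell_t2", n_animals=2, n_steps=60, seed=11)
    return sd.simulate_dataset(spec)


@pytest.fixture(scope="session")
def tiny_haulout_fit(tiny_haulout_dataset):
    data = tiny_haulout_dataset.model_data()
    cfg = SamplerConfig.desk(seed=3, n_iter=300, n_burn=150, thin=3)
    return fit_model(data, cfg, PriorConfig(theta2_informative=True))


@pytest.fixture(scope="session")
def tiny_activity_dataset():
    spec = sd.preset("afs_t2", n_animals=2, n_steps=60, seed=12)
    return sd.simulate_dataset(spec)


@pytest.fixture(scope="session")
def tiny_activity_fit(tiny_activity_dataset):
    data = tiny_activity_dataset.model_data()
    cfg = SamplerConfig.desk(seed=4, n_iter=300, n_burn=150, thin=3)
    return fit_model(data, cfg, PriorConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
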