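import numpy as np
import pytest

from rsnvar.synthetic import SimulationConfig, make_atlas, simulate_run


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def atlas(default_config):
    return make_atlas(default_config)


@pytest.fixture(scope="session")
def clean_config():
    """High-SNR session used by recovery tests."""
    return SimulationConfig(snr=10.0, n_artifact_sources=3)


@pytest.fixture(scope="session")
def clean_run(clean_config):
    atlas = make_atlas(clean_config)
    series, truth = simulate_run(atlas, clean_config, seed=7)
    return atlas, series, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
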