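import dataclasses

import pytest
from hypothesis import settings

from coroflow import SimulationConfig

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def noise_free_config(config):
    return dataclasses.replace(
        config, beat_noise_sd_velocity=0.0, beat_noise_sd_pressure=0.0
    )
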