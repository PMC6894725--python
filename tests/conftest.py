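import dataclasses

import pytest

from fraxval import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(n_participants=20_000, seed=11)


@pytest.fixture(scope="session")
def cohort(default_config):
    """Moderate default-parameter cohort shared across tests."""
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def uncensored_config():
    """Censor-free generator so observed outcomes equal latent outcomes."""
    return GeneratorConfig(
        n_participants=50_000,
        seed=29,
        dropout_rate_annual=0.0,
        death_rate_annual=0.0,
    )


@pytest.fixture(scope="session")
def uncensored_cohort(uncensored_config):
    return generate_cohort(uncensored_config)


@pytest.fixture
def tiny_config():
    return GeneratorConfig(n_participants=200, seed=5)


def replace(config, **kwargs):
    return dataclasses.replace(config, **kwargs)
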