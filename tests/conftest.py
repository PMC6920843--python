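import numpy as np
import pytest

from nmrdfit.synthetic import GeneratorConfig, simulate_profile, table1_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return table1_fixtures()


@pytest.fixture(scope="session")
def elastin(fixtures):
    return fixtures["elastin"]


@pytest.fixture(scope="session")
def lysozyme(fixtures):
    return fixtures["lysozyme"]


@pytest.fixture(scope="session")
def elastin_profile(elastin):
    """Noiseless default-grid elastin profile."""
    return simulate_profile(elastin, GeneratorConfig())


@pytest.fixture(scope="session")
def lysozyme_profile(lysozyme):
    return simulate_profile(lysozyme, GeneratorConfig())


@pytest.fixture(scope="session")
def dense_lysozyme_profile(lysozyme):
    """Noiseless lysozyme profile with >= 200 points inside 1.5-3.5 MHz."""
    config = GeneratorConfig(
        n_points=60, densify_factor=40, densify_window=(1.5, 3.5)
    )
    profile = simulate_profile(lysozyme, config)
    n_in = int(((profile.frequencies >= 1.5) & (profile.frequencies <= 3.5)).sum())
    assert n_in >= 200
    return profile
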