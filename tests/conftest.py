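import pytest

import hfsim


@pytest.fixture(scope="session")
def config():
    return hfsim.default_config()


@pytest.fixture(scope="session")
def small_cohort(config):
    return hfsim.generate_population(
        config.population, 60, seed=11, productivity=config.productivity
    )


@pytest.fixture(scope="session")
def patient(small_cohort):
    return small_cohort[0]
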