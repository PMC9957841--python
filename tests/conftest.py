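import pytest
from hypothesis import HealthCheck, settings

from pgxstar import datasets

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return datasets.load_default_catalog()


@pytest.fixture(scope="session")
def global_table():
    return datasets.load_global_frequency_table()


@pytest.fixture(scope="session")
def population_table():
    return datasets.load_ssa_population_table()


@pytest.fixture(scope="session")
def novel_recipes(catalog):
    return datasets.load_novel_recipes(catalog)
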