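import pytest
from hypothesis import HealthCheck, settings

from fedimer import datasets
from fedimer.synthetic import default_study_spec, gen_study

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def basis_records():
    return datasets.basis_records()


@pytest.fixture(scope="session")
def spin_table():
    return datasets.spin_state_table()


@pytest.fixture(scope="session")
def composite_block():
    return datasets.composite_table()


@pytest.fixture(scope="session")
def study_bundle():
    """Noiseless synthetic study with its analytic answer key."""
    return gen_study(default_study_spec(seed=7))
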