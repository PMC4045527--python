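import pytest
from hypothesis import HealthCheck, settings

import fetaldose as fd

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("deterministic")

FIXTURE_SEED = 20260930


@pytest.fixture(scope="session")
def fixture_text() -> str:
    return fd.generate_fixture_tables(seed=FIXTURE_SEED, n_projections=8, n_scanners=3)


@pytest.fixture(scope="session")
def store(fixture_text) -> fd.CoefficientStore:
    return fd.loads_tables(fixture_text)


@pytest.fixture
def ctx() -> fd.PatientContext:
    return fd.PatientContext(ga_weeks=20.0, fetal_depth_cm=7.0, maternal_ap_cm=24.0)
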