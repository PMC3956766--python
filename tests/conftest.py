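import pytest
from hypothesis import HealthCheck, settings

import menomark as mm

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ref_config():
    return mm.load_config()


@pytest.fixture(scope="session")
def eq5d_spec():
    return mm.load_reference_spec("eq5d")


@pytest.fixture(scope="session")
def sf6d_spec():
    return mm.load_reference_spec("sf6d")


@pytest.fixture(scope="session")
def eq5d_result(eq5d_spec):
    return mm.evaluate_spec(eq5d_spec)


@pytest.fixture(scope="session")
def sf6d_result(sf6d_spec):
    return mm.evaluate_spec(sf6d_spec)


@pytest.fixture(scope="session")
def lng_model(eq5d_spec):
    return eq5d_spec.arm(mm.ARM_LNG).transitions


@pytest.fixture(scope="session")
def usual_model(eq5d_spec):
    return eq5d_spec.arm(mm.ARM_USUAL).transitions
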