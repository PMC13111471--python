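import pytest

from viscowin import JointSpec, load_reference_formulations


@pytest.fixture(scope="session")
def formulations():
    """Packaged reference products keyed by name (HA-A … HA-D)."""
    return {f.name: f for f in load_reference_formulations()}


@pytest.fixture
def knee():
    return JointSpec(joint_type="knee", synovial_volume=6.0, injected_volume=3.0)


@pytest.fixture
def hip():
    return JointSpec(joint_type="hip", synovial_volume=4.0, injected_volume=2.0)
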