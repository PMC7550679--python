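import pytest

from fearcircuit import SimConfig, build_default_circuit
from fearcircuit.experiments import ExperimentContext


@pytest.fixture(scope="session")
def model():
    return build_default_circuit()


@pytest.fixture()
def cfg():
    return SimConfig()


@pytest.fixture(scope="session")
def ctx():
    """Shared control pipeline (the unperturbed four-session paradigm).

    Session-scoped: the standard run, its probes and PSP measurements
    are computed once and reused by behavioral and acceptance tests.
    """
    return ExperimentContext()
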