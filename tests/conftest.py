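import pytest

from mhsd.engine import IntegrationConfig
from mhsd.model import run
from mhsd.params import ModelParameters


@pytest.fixture(scope="session")
def default_params():
    return ModelParameters()


@pytest.fixture(scope="session")
def fast_config():
    """Coarser step used where only qualitative behaviour matters."""
    return IntegrationConfig(dt=0.25, record_every=4)


@pytest.fixture(scope="session")
def baseline_traj(default_params):
    """Business-as-usual pre-pandemic run at the reporting step."""
    return run(default_params)
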