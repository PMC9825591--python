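import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, database=None, deadline=None)
settings.load_profile("repro")

from dimergel.fcs import default_detection_volume
from dimergel.model_core import ModelParams
from dimergel.phase_diagram import compute_binodal


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def binodal(params):
    """Default-parameter binodal, shared across the suite (a few seconds to build)."""
    return compute_binodal(params)


@pytest.fixture(scope="session")
def detection():
    return default_detection_volume()
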