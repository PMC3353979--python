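import pytest

from paleosweep.demography import load_packaged_model
from paleosweep.wf_engine import compile_model


@pytest.fixture(scope="session")
def ooa_model():
    """The packaged scaled Out-of-Africa demographic model."""
    return load_packaged_model()


@pytest.fixture(scope="session")
def ooa_compiled(ooa_model):
    """Compiled per-generation schedules for the packaged model."""
    return compile_model(ooa_model)
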