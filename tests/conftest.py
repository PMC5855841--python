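import pytest

from cavgate.gating_model import make_presets


@pytest.fixture(scope="session")
def presets():
    return make_presets()


@pytest.fixture(scope="session")
def vehicle(presets):
    return presets["vehicle"]
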