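import pytest

from rbcage.calibration import published_model
from rbcage.kinetics import anchored_params


@pytest.fixture(scope="session")
def published():
    return published_model()


@pytest.fixture(scope="session")
def anchored():
    return anchored_params()
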