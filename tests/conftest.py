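import numpy as np
import pytest

from hdemg.grid import Anthropometrics, grid_from_anthropometrics
from hdemg.session import ContractionProtocol


@pytest.fixture
def anth():
    return Anthropometrics(forearm_length_cm=25.0, circumference_cm=26.0)


@pytest.fixture
def grid(anth):
    return grid_from_anthropometrics(
        anth.forearm_length_cm, anth.circumference_cm, anth.handedness
    )


@pytest.fixture
def short_protocol():
    """Three repetitions at 1024 Hz: a fast but complete on/off protocol."""
    return ContractionProtocol(n_repetitions=3, fs=1024.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
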