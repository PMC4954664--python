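import numpy as np
import pytest

from aukforage import synthetic_data as sd


@pytest.fixture
def cfg():
    return sd.ScenarioConfig(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
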