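import numpy as np
import pytest

from brspike.synthdata import Recording, pure_sinusoid

#: Published per-condition complex-channel statistics:
#: condition -> (amplitude mean mV, amplitude SD mV, period mean s, period SD s)
PAPER_STATS = {
    "green": (7.31, 1.49, 645.23, 16.32),
    "blue": (3.64, 2.69, 647.23, 14.38),
    "yellow": (3.99, 2.25, 662.48, 11.60),
    "red": (1.68, 1.06, 649.61, 11.47),
}


@pytest.fixture(scope="session")
def sinusoid_600() -> Recording:
    """Noiseless 10 mV sinusoid, period 600 s, 1 Hz sampling, 24 h."""
    return pure_sinusoid(10.0, 600.0, 86_400.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
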