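import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def random_rr(rng):
    """A plausible random murine RR segment (ms)."""
    return 100.0 + 5.0 * rng.standard_normal(300)
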