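import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_series(rng):
    """Small 3-variable recording of correlated noise."""
    base = rng.normal(size=200)
    values = np.vstack([
        base + 0.5 * rng.normal(size=200),
        base + 0.5 * rng.normal(size=200),
        rng.normal(size=200),
    ])
    return values
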