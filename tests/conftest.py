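import numpy as np
import pytest

from metrano.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def tiny_phantom():
    """One deterministic 64³ phantom scan (volume, labels, truth)."""
    return generate_phantom(PhantomConfig.tiny(), seed=7)


@pytest.fixture(scope="session")
def measurable_config():
    """Tiny profile restricted to measurable (>= 5 mm) lesions."""
    return PhantomConfig.tiny(diameter_range_mm=(6.0, 12.0))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
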