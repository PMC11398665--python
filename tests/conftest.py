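import numpy as np
import pytest
from hypothesis import settings

from strtomo.layout import generate_layout

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_layout():
    """One default ten-subunit layout, shared across read-only tests."""
    return generate_layout(10, np.random.default_rng(42))
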