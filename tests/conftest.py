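import numpy as np
import pytest

from srnabench.pool import ReferencePool, build_reference_pool


@pytest.fixture(scope="session")
def small_pool() -> ReferencePool:
    """20 random references, 16-28 nt, for assignment/dedup tests."""
    return build_reference_pool(20, (16, 28), (0.2, 0.8), seed=5)


@pytest.fixture(scope="session")
def default_pool() -> ReferencePool:
    """The default 962-sequence equimolar pool."""
    return build_reference_pool(962, (16, 28), (0.2, 0.8), seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
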