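import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_phantom():
    """One deterministic phantom shared by read-only tests."""
    from carotexture.synth import PhantomSpec, generate_wall_phantom

    return generate_wall_phantom(PhantomSpec(seed=7))
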