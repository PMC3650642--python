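import numpy as np
import pytest

from habseg import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """The fixed-seed default phantom (noise at its default level)."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def noise_free_phantom():
    """Default geometry without noise, for exact-recovery checks."""
    return generate_phantom(PhantomSpec(seed=11, noise_sigma=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
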