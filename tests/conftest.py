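import numpy as np
import pytest

from nmsn.synthetic import PhantomSpec, generate_phantom

# one project-wide base seed for every stochastic check
SEED = 922


@pytest.fixture(scope="session")
def default_phantom():
    """One rendered phantom (image + masks) at the default spec, with noise."""
    spec = PhantomSpec()
    image, masks = generate_phantom(spec, seed=SEED)
    return spec, image, masks


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = PhantomSpec(bnd_sd=0.0)
    image, masks = generate_phantom(spec, seed=SEED)
    return spec, image, masks


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
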