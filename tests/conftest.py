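import numpy as np
import pytest

from shearfocus import PhantomSpec, SweepSpec, make_phantom, make_stack


@pytest.fixture(scope="session")
def default_phantom():
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def default_stack(default_phantom):
    return make_stack(default_phantom, SweepSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def random_image(rng):
    return rng.random((64, 64))
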