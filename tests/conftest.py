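import numpy as np
import pytest

from vectex import PhantomSpec, ROIMask, VTI, Volume, make_phantom


@pytest.fixture()
def rng():
    # fresh generator per test: deterministic and order-independent
    return np.random.default_rng(20220614)


@pytest.fixture()
def random_volume(rng):
    return Volume(data=rng.normal(size=(8, 8, 8)) * 50.0)


@pytest.fixture()
def random_vti(rng):
    ch0 = rng.integers(0, 3, size=(8, 8, 8))
    ch1 = rng.integers(0, 4, size=(8, 8, 8))
    return VTI(kind="GAV", channels=[ch0, ch1], levels=[3, 4])


@pytest.fixture()
def partial_roi(rng):
    mask = rng.random((8, 8, 8)) > 0.3
    mask[0, 0, 0] = True  # guarantee non-empty
    return ROIMask(mask=mask)


@pytest.fixture()
def full_roi():
    return ROIMask(mask=np.ones((8, 8, 8), dtype=bool))


@pytest.fixture(scope="session")
def small_phantom():
    spec = PhantomSpec(shape=(20, 20, 20), lesion_radius=6.0, seed=5)
    return make_phantom(spec)
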