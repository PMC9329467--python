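import numpy as np
import pytest

from sketchct.phantoms import PhantomSpec, make_phantom, make_paired_dataset
from sketchct.preprocess import preprocess_volume


@pytest.fixture(scope="session")
def phantom20():
    """A 20 mm tumor phantom on anisotropic (0.625, 0.625, 0.5) spacing."""
    return make_phantom(PhantomSpec(tumor_long_diameter_mm=20.0, seed=1))


@pytest.fixture(scope="session")
def small_pairs32():
    """20 (sketch, CT) pairs at 32x32 from phantoms, one slice per tumor."""
    dataset = make_paired_dataset(20, seed=3)
    return [preprocess_volume(vol, train_mode=False, size=32)[0]
            for vol, _ in dataset]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
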