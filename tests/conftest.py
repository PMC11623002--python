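import numpy as np
import pytest

from splitfed.phantom import PhantomSpec, generate_phantom_dataset


@pytest.fixture(scope="session")
def small_phantom():
    """Balanced 3-class phantom set, 32x32, 12 per class."""
    return generate_phantom_dataset(
        PhantomSpec(image_size=32, n_per_class=(12, 12, 12), seed=100))


@pytest.fixture(scope="session")
def imbalanced_phantom():
    """Imbalanced phantom set mirroring the 0.28 / 0.02 class ratios."""
    return generate_phantom_dataset(
        PhantomSpec(image_size=32, n_per_class=(100, 28, 2), seed=101))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
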