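import numpy as np
import pytest

from mwbrain.synthetic_data import PhantomSpec, generate_dataset


@pytest.fixture(scope="session")
def small_spec():
    """64-px phantom spec used by most dataset-level tests."""
    return PhantomSpec(image_size=64)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    """30 balanced 64-px samples, fixed seed."""
    return generate_dataset(n_per_class=10, seed=123, spec=small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
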