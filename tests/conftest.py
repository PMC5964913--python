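import numpy as np
import pytest

from pelviseg import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_phantom():
    """A compact phantom sequence used by several module tests: 12 slices,
    one topology change, moderate image size for speed."""
    spec = PhantomSpec(
        n_slices=12,
        topology_schedule=((1, 2), (7, 3)),
        image_shape=(96, 96),
        seed=4,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def default_phantom():
    """One default-sized phantom slice set (study conditions) for
    segmentation-quality checks."""
    spec = PhantomSpec(
        n_slices=4,
        topology_schedule=((1, 3),),
        seed=9,
    )
    return generate_phantom(spec)
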