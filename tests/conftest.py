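import numpy as np
import pytest

from ribseg.synthetic_phantom import PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(42)


# desk-scale phantom used by the learning tests: 64px slices with ribs large
# enough that a crack spans a learnable number of pixels
TRAIN_SPEC = PhantomSpec(
    image_size=64,
    fracture_probability=0.7,
    n_ribs=(8, 10),
    rib_length_frac=0.11,
    rib_thickness_frac=0.06,
    crack_width=2,
)


@pytest.fixture(scope="session")
def train_spec():
    return TRAIN_SPEC
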