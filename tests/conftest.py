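import numpy as np
import pytest

from tractsheet.skeleton import extract_medial_surface
from tractsheet.synthetic import SheetPhantomSpec, make_sheet_phantom


@pytest.fixture(scope="session")
def flat_phantom():
    """Default flat-slab phantom: (TensorVolume, SheetTruth)."""
    return make_sheet_phantom(SheetPhantomSpec())


@pytest.fixture(scope="session")
def flat_surface(flat_phantom):
    _, truth = flat_phantom
    return extract_medial_surface(truth.mask)


@pytest.fixture(scope="session")
def small_surface():
    """A small (~500 vertex) skeleton for statistics tests."""
    _, truth = make_sheet_phantom(SheetPhantomSpec(dims=(22, 22, 19)))
    return extract_medial_surface(truth.mask)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
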