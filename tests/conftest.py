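import numpy as np
import pytest

from plasmux import BarcodeReference, BarcodeScheme
from plasmux.simulate import SimConfig, make_library


@pytest.fixture(scope="session")
def scheme() -> BarcodeScheme:
    return BarcodeScheme()


@pytest.fixture(scope="session")
def ref() -> BarcodeReference:
    return BarcodeReference()


@pytest.fixture(scope="session")
def intact_library(ref):
    """An intact (defect-free) simulated plasmid library of 500 molecules."""
    config = SimConfig(
        n_library_molecules=500,
        large_deletion_fraction=0.0,
        small_deletion_fraction=0.0,
        seed=101,
    )
    return make_library(config, ref, np.random.default_rng(101))
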