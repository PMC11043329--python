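import numpy as np
import pytest

from qmnase.annotation import GeneRecord
from qmnase.simulate import SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def plus_gene():
    return GeneRecord("Neb", "chr_Neb", 6000, "+", "skeletal")


@pytest.fixture
def minus_gene():
    return GeneRecord("Ttn", "chr_Ttn", 6000, "-", "common")


@pytest.fixture
def small_spec():
    """Reduced depth for fast fragment-level tests."""
    return SyntheticSpec(depth=1000, chip_depth=1000)
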