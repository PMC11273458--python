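import numpy as np
import pytest

from armlearn.encoding import PropertyTable
from armlearn.variant_space import VariantSpace, sav_space


@pytest.fixture(scope="session")
def space() -> VariantSpace:
    return sav_space()


@pytest.fixture(scope="session")
def toy_space() -> VariantSpace:
    """3 positions over a 4-letter alphabet: small enough for brute force."""
    return VariantSpace(positions=(1, 2, 3), reference="AAA", wild_type="CCC", alphabet="ACDE")


@pytest.fixture(scope="session")
def property_table() -> PropertyTable:
    return PropertyTable.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
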