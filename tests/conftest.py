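import numpy as np
import pytest

from sesgb.fixtures import make_born_ion, make_toy_complex, make_toy_solute
from sesgb.gb_energy import SolventParams


@pytest.fixture(scope="session")
def born_ion():
    return make_born_ion(1.0, 2.0)


@pytest.fixture(scope="session")
def saltless():
    return SolventParams(salt_molar=0.0)


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(6, 2, seed=7)


@pytest.fixture(scope="session")
def toy_solute():
    return make_toy_solute(4, seed=5)
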