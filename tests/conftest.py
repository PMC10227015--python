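import numpy as np
import pytest

from analogkit.chem import Molecule
from analogkit.fixtures import MASITINIB_SMILES, small_dictionary_spec
from analogkit.library import build_generic_dictionary


@pytest.fixture(scope="session")
def benzene():
    return Molecule.from_smiles("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def masitinib():
    return Molecule.from_smiles(MASITINIB_SMILES, "masitinib")


@pytest.fixture(scope="session")
def small_dictionary():
    return build_generic_dictionary(small_dictionary_spec())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
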