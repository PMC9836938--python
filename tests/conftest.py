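import pytest

from macrocode.chemistry import load_registry
from macrocode.design import CyclicSpecies
from macrocode.io import load_schemes


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def schemes():
    return load_schemes()


@pytest.fixture(scope="session")
def depsi_ring(registry):
    """A 5-ring with one ncAA, one hydroxy acid and three canonical
    residues — the geometry of the sequenced cyclic depsipeptide."""
    return CyclicSpecies("depsi5", ("L", "A", "V", "8", "5"), registry)


@pytest.fixture(scope="session")
def peptide_ring(registry):
    """An all-amide 5-ring (no ester bonds)."""
    return CyclicSpecies("pep5", ("L", "A", "V", "2", "5"), registry)
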