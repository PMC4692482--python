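import pytest

from tpistab.sedeq import HomogeneousModel
from tpistab.synth import StudyDesign, synthetic_construct_counts, synthetic_reference_pair


@pytest.fixture(scope="session")
def design():
    """The default equilibrium-run design (2 speeds x 3 loadings)."""
    return StudyDesign()


@pytest.fixture(scope="session")
def dimer_truth(design):
    return HomogeneousModel(monomer_mass=design.monomer_mass, n=2)


@pytest.fixture(scope="session")
def construct_counts():
    return synthetic_construct_counts()


@pytest.fixture(scope="session")
def reference_pair():
    """Synthetic apo / ligand-bound structure pair (expensive; share it)."""
    return synthetic_reference_pair()
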