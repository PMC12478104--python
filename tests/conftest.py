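import pytest

from amyloidscan.reference import ReferenceConstruct
from amyloidscan.synthetic import SelectionDesign, simulate_ground_truth


@pytest.fixture(scope="session")
def ref():
    return ReferenceConstruct.abeta42()


@pytest.fixture(scope="session")
def tiny_ref():
    """A short POI with a short linker: fast read-level tests."""
    return ReferenceConstruct("ACDEFGHI", linker_sequence="GSSG")


@pytest.fixture(scope="session")
def truth(ref):
    return simulate_ground_truth(ref, seed=7)


@pytest.fixture(scope="session")
def small_design():
    return SelectionDesign(read_depth=8000, n_replicates=2)
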