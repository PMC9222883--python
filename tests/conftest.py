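import numpy as np
import pytest
from hypothesis import settings

from omegascan.codon_core import CodonAlignment, STANDARD_CODE, equal_frequencies
from omegascan.codon_models import make_mixture
from omegascan.simulator import SimulationSpec, simulate_alignment, three_taxon_tree
from omegascan.tree_topologies import parse_newick

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def code():
    return STANDARD_CODE


@pytest.fixture(scope="session")
def uniform_pi():
    return equal_frequencies(STANDARD_CODE)


@pytest.fixture
def toy_alignment():
    return CodonAlignment(
        taxa=["Out", "A", "B"],
        codons=[
            ["ATG", "AAA", "CCT"],
            ["ATG", "AAG", "CCT"],
            ["ATA", "AAA", "CCA"],
        ],
    )


@pytest.fixture(scope="session")
def star_tree():
    return three_taxon_tree(0.3)


@pytest.fixture(scope="session")
def neutral_alignment(star_tree):
    """200 codons simulated under strict neutrality (omega = 1)."""
    spec = SimulationSpec(
        tree=star_tree,
        mixture=make_mixture("M0", kappa=2.0, omega=1.0),
        n_codons=200,
        seed=20260929,
    )
    alignment, _ = simulate_alignment(spec)
    return alignment


@pytest.fixture(scope="session")
def quartet_tree():
    return parse_newick("((A:0.2,B:0.15):0.1,C:0.25,D:0.3);")
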