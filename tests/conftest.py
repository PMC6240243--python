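import numpy as np
import pytest

from famevo import simulate as sim
from famevo.trees import DatedSpeciesTree


@pytest.fixture(scope="session")
def species_tree_11():
    """The bundled 11-taxon dated species tree (topology A)."""
    return sim.hypocreales_tree("A")


@pytest.fixture(scope="session")
def species_tree_4():
    return DatedSpeciesTree.from_newick("(((A:1,B:1):1,C:2):1,D:3);")


@pytest.fixture(scope="session")
def tree_6taxa_sub():
    """Six-taxon tree with substitution-scale branch lengths."""
    return DatedSpeciesTree.from_newick(
        "(((s1:0.15,s2:0.15):0.1,(s3:0.15,s4:0.15):0.1):0.05,(s5:0.2,s6:0.2):0.1);"
    )


@pytest.fixture(scope="session")
def tree_11_sub(species_tree_11):
    """The 11-taxon tree rescaled to ~0.5 substitutions/site root height."""
    height = max(species_tree_11.depths()[t] for t in species_tree_11.leaves)
    node = species_tree_11.mrca(["HMI", "HSI"])
    age = species_tree_11.node_ages()[node]
    return species_tree_11.calibrate("HMI", "HSI", age / height * 0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
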