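import numpy as np
import pytest

from phylocurate import (
    Alignment,
    parse_newick,
    poisson_model,
    simulate_alignment,
    simulate_tree,
)


@pytest.fixture(scope="session")
def poisson1():
    return poisson_model(K=1)


@pytest.fixture(scope="session")
def poisson_g4():
    return poisson_model(alpha=1.0, K=4)


@pytest.fixture(scope="session")
def tree5():
    """5-leaf unrooted tree with distinct branch lengths."""
    return parse_newick("((A:0.1,B:0.2):0.05,(C:0.15,D:0.25):0.1,E:0.3);")


@pytest.fixture(scope="session")
def small_gene(poisson1):
    tree = simulate_tree(8, seed=11, height=0.6)
    aln, cats = simulate_alignment(tree, poisson1, 300, seed=12)
    return tree, aln, cats


@pytest.fixture
def toy_alignment():
    return Alignment(
        ["A", "B", "C", "D"],
        np.array(
            [
                list("ARNDAR"),
                list("ARNDCR"),
                list("ARNECQ"),
                list("ARXE-Q"),
            ]
        ),
    )
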