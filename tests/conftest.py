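import numpy as np
import pytest

from phylorecomb import synthetic, two_locus_table
from phylorecomb.tree import parse_newick

RHO_GRID = (0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0)


@pytest.fixture
def cherry():
    return parse_newick("(A:1.0,B:1.0);")


@pytest.fixture
def three_tip():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star4():
    return parse_newick("(A:1,B:1,C:1,D:1);")


@pytest.fixture
def balanced4():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def yule50():
    return synthetic.yule_tree(50, 1.0, seed=42)


@pytest.fixture(scope="session")
def twolocus_n30():
    """Shared two-locus configuration table for n = 30 chromosomes.

    Built once per session (Monte-Carlo, 10k replicates per grid point);
    used by every composite-likelihood test.
    """
    return two_locus_table(30, RHO_GRID, mc_reps=10_000, seed=20_300)


def brute_force_mrca_depth(tree, tip_i, tip_j):
    """Independent oracle: sum of branch lengths root -> MRCA."""
    def ancestors(node):
        path = []
        while node != -1:
            path.append(node)
            node = tree.parent[node]
        return path

    ai = ancestors(tip_i)
    aj = set(ancestors(tip_j))
    mrca = next(n for n in ai if n in aj)
    depth = 0.0
    node = mrca
    while node != tree.root:
        depth += tree.branch_length[node]
        node = tree.parent[node]
    return depth
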