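import numpy as np
import pytest

from hsfkit import reconcile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def stree_ab():
    return reconcile.species_tree_from_newick("(A,B);")


@pytest.fixture
def stree_abc():
    return reconcile.species_tree_from_newick("((A,B),C);")


@pytest.fixture
def stree_abcd():
    return reconcile.species_tree_from_newick("((A,B),(C,D));")
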