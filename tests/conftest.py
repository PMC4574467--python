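import numpy as np
import pytest

from softwired.matrix import CharacterMatrix, CostMatrix
from softwired.io import parse_enewick

# the worked 4-taxon, 1-reticulation example used throughout:
# displays ((A,B),(C,D)) and (A,((B,C),D))
TOY_NEWICK = "((A,(B)#H1),((#H1,C),D));"

# character patterns: c1 splits AB|CD, c2 splits AD|BC
C1 = {"A": "0", "B": "0", "C": "1", "D": "1"}
C2 = {"A": "0", "B": "1", "C": "1", "D": "0"}


def matrix_from_columns(*cols) -> CharacterMatrix:
    taxa = sorted(cols[0])
    seqs = [(t, "".join(c[t] for c in cols)) for t in taxa]
    return CharacterMatrix.from_sequences(seqs)


@pytest.fixture
def toy_network():
    return parse_enewick(TOY_NEWICK)


@pytest.fixture
def toy_matrix_c112():
    """[c1, c1, c2]: softwired 3, tree 4, penalty 1/6."""
    return matrix_from_columns(C1, C1, C2)


@pytest.fixture
def toy_matrix_c11():
    """[c1, c1]: unused network edge, penalty infinite."""
    return matrix_from_columns(C1, C1)


@pytest.fixture
def unit_costs():
    return CostMatrix.unit()


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def random_instance(rng, max_leaves=8, max_retics=2, max_chars=20, max_states=4,
                    min_leaves=4):
    """Random (network, matrix) diagnosis instance."""
    from softwired.simulate import random_network

    n = int(rng.integers(min_leaves, max_leaves + 1))
    r = int(rng.integers(0, max_retics + 1))
    net = random_network(n, r, rng)
    k = int(rng.integers(1, max_chars + 1))
    s = int(rng.integers(2, max_states + 1))
    states = "0123"[:s]
    labels = sorted(net.leaf_labels.values())
    seqs = [
        (lab, "".join(states[i] for i in rng.integers(0, s, size=k)))
        for lab in labels
    ]
    return net, CharacterMatrix.from_sequences(seqs)
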