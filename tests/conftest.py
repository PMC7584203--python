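import numpy as np
import pytest

from permnet import BiDegreeSequence

# 9-node demonstration network: in/out degree targets whose sums are both 23;
# node 8 (1-based) has k_out = 9 = N, forcing a self-loop in any binary
# realisation.
TOY_K_IN = [2, 2, 3, 3, 5, 2, 2, 2, 2]
TOY_K_OUT = [1, 4, 1, 1, 1, 2, 3, 9, 1]

# The five binary realisations of k_in = k_out = [1 2 1] (self-loops allowed).
REALISATIONS_121 = [
    ((0, 1, 0), (1, 0, 1), (0, 1, 0)),
    ((0, 1, 0), (1, 1, 0), (0, 0, 1)),
    ((1, 0, 0), (0, 1, 1), (0, 1, 0)),
    ((0, 0, 1), (1, 1, 0), (0, 1, 0)),
    ((0, 1, 0), (0, 1, 1), (1, 0, 0)),
]

# A worked two-step example: this start has exactly two feasible transfers
# out of donor column 0, and its two daughters have 2 and 1 follow-up moves.
START_EXAMPLE = np.array([[1, 0, 0], [1, 0, 1], [0, 0, 1]])


@pytest.fixture
def seq121():
    return BiDegreeSequence([1, 2, 1], [1, 2, 1])


@pytest.fixture
def toy_seq():
    return BiDegreeSequence(TOY_K_IN, TOY_K_OUT)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
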