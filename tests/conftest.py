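import numpy as np
import pytest

import demefix as dx


@pytest.fixture
def clique5():
    return dx.make_clique(5, 0.2)


@pytest.fixture
def star_suppressor():
    """Star with stronger incoming than outgoing migration (alpha=4)."""
    return dx.make_star(dx.StarSpec(D=5, mO=0.05, alpha=4.0))


@pytest.fixture
def wellmixed_graph():
    """Single-deme graph: the well-mixed baseline."""
    return dx.MigrationGraph(m=np.array([[1.0]]))
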