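import networkx as nx
import numpy as np
import pytest

from granet.preprocess import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix():
    return ExpressionMatrix(
        ["g1", "g2", "g3"],
        np.array([[1.0, 3.0, 6.0, 10.0], [2.0, 2.0, 2.0, 2.0], [0.0, 1.0, 0.0, 1.0]]),
        ["t1", "t2", "t3", "t4"],
    )


@pytest.fixture
def k5():
    return nx.complete_graph(5)


@pytest.fixture
def bridged_k4s():
    """Two K4s ({0..3}, {4..7}) joined by the single bridge edge 3-4."""
    g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
    g.add_edge(3, 4)
    return g
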