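import numpy as np
import pytest

from bimod import DirectedGraph


def random_directed_graph(rng, n, density=0.3, weighted=False):
    """Random directed graph with no self-loops; weights in (0, 2] if weighted."""
    A = (rng.random((n, n)) < density).astype(float)
    np.fill_diagonal(A, 0.0)
    if weighted:
        A *= rng.uniform(0.1, 2.0, size=(n, n))
    if A.sum() == 0:  # guarantee m > 0
        i, j = rng.integers(0, n), rng.integers(0, n - 1)
        A[i, (i + 1 + j) % n] = 1.0
    return DirectedGraph(list(range(n)), A)


def random_symmetric_graph(rng, n, density=0.3):
    """Random undirected (symmetric binary) graph with at least one edge."""
    U = np.triu((rng.random((n, n)) < density).astype(float), k=1)
    A = U + U.T
    if A.sum() == 0:
        A[0, 1] = A[1, 0] = 1.0
    return DirectedGraph(list(range(n)), A)


@pytest.fixture
def four_node():
    """The worked example: nodes 1..4, edges 1->3 and 2->4 (m=2)."""
    A = np.zeros((4, 4))
    A[0, 2] = 1.0
    A[1, 3] = 1.0
    return DirectedGraph([1, 2, 3, 4], A)


@pytest.fixture
def two_triangles():
    """Two undirected triangles {1,2,3} and {4,5,6} joined by edge 3-4.

    Symmetric adjacency; 7 undirected edges, so directed m = 14.
    """
    A = np.zeros((6, 6))
    und = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]
    for i, j in und:
        A[i, j] = A[j, i] = 1.0
    return DirectedGraph([1, 2, 3, 4, 5, 6], A)
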