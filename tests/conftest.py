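import numpy as np
import pytest

from spatialcut.data_io import SpatialExpressionMatrix
from spatialcut.spatial_graph import NeighborGraph, build_delaunay_graph


@pytest.fixture
def tiny_matrix():
    """3 spots, 2 genes, coordinate-encoded spot ids."""
    return SpatialExpressionMatrix(
        coords=np.array([[1.0, 1.0], [1.0, 2.0], [2.0, 1.0]]),
        counts=np.array([[1.0, 0.0], [2.0, 3.0], [4.0, 5.0]]),
        gene_ids=["g1", "g2"],
        spot_ids=["1x1", "1x2", "2x1"],
    )


@pytest.fixture
def square_graph():
    """Unit square corners: 4 sides + 1 diagonal after triangulation."""
    return build_delaunay_graph(
        np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    )


@pytest.fixture
def path_graph():
    """5-node path graph with dummy collinear-free coords."""
    coords = np.array([[i, (i % 2) * 0.1] for i in range(5)], dtype=float)
    edges = np.array([[i, i + 1] for i in range(4)])
    return NeighborGraph(n=5, edges=edges, coords=coords)


def random_graph(rng, n):
    """Random connected graph on n nodes (spanning tree + extra edges)."""
    edges = {(int(rng.integers(0, i)), i) for i in range(1, n)}
    for _ in range(n):
        a, b = rng.integers(0, n, 2)
        if a != b:
            edges.add((min(int(a), int(b)), max(int(a), int(b))))
    coords = rng.random((n, 2)) * 10
    return NeighborGraph(n=n, edges=np.array(sorted(edges)), coords=coords)
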