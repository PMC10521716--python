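import numpy as np
import pytest
import scipy.sparse as sp

from sgcp.graphdata import RegionGraph
from sgcp.synthetic import SyntheticConfig, make_region


def graph_from_edges(n, edges, n_feat=4, seed=0, labels=None, coords=None):
    """Small RegionGraph with given undirected edges and random count features."""
    rng = np.random.default_rng(seed)
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return RegionGraph(
        adjacency=sp.csr_matrix(a),
        features=rng.integers(0, 10, size=(n, n_feat)),
        coords=coords if coords is not None else rng.normal(size=(n, 3)),
        labels=labels,
    )


@pytest.fixture
def path3():
    """Path graph a-b-c."""
    return graph_from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def k4():
    """Complete graph on 4 nodes."""
    return graph_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])


@pytest.fixture
def random_graph():
    """Seeded Erdos-Renyi-style 20-node graph with features and coords."""
    rng = np.random.default_rng(42)
    n = 20
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.3
    ]
    return graph_from_edges(n, edges, n_feat=6, seed=7)


@pytest.fixture
def small_region():
    """Small labelled synthetic region (fast to embed)."""
    cfg = SyntheticConfig(grid_shape=(6, 6, 5), n_rois=34, signature_size=3, seed=3)
    return make_region(cfg, region_id="SMALL")


@pytest.fixture
def small_config():
    return SyntheticConfig(grid_shape=(6, 6, 5), n_rois=34, signature_size=3, seed=3)
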