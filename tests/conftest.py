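import numpy as np
import pytest

from connfp import CohortConfig, null_volume_params
from connfp.network import BinaryNetwork


def union_find_connected(adjacency: np.ndarray) -> bool:
    """Independent connectivity oracle (disjoint-set forest)."""
    n = adjacency.shape[0]
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if adjacency[i, j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    return len({find(i) for i in range(n)}) == 1


def random_connected_network(rng: np.random.Generator, n_max: int = 12) -> BinaryNetwork:
    """A random connected undirected graph wrapped as a BinaryNetwork."""
    while True:
        n = int(rng.integers(3, n_max + 1))
        p = float(rng.uniform(0.25, 0.8))
        adj = (rng.random((n, n)) < p).astype(np.int8)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        if union_find_connected(adj):
            names = [f"n{i}" for i in range(n)]
            m = n * (n - 1) // 2
            return BinaryNetwork(adj, adj.sum() / 2 / m, names)


@pytest.fixture
def small_null_config():
    """A fast, fully exchangeable cohort configuration."""
    return CohortConfig(
        n_per_group={"NC": 8, "MCI": 8, "AD": 8},
        n_rois=20, n_timepoints=60, group_effects=[],
        volume_params=null_volume_params(), seed=0)
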