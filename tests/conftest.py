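import numpy as np
import pytest

from hypersis import Hypergraph, PartitionedHypergraph, random_hypergraph


@pytest.fixture
def h3():
    """Three nodes, hyperedges {0,1,2} and {0,1}; W = [[2,2,1],[2,2,1],[1,1,1]]."""
    return Hypergraph(3, [frozenset({0, 1, 2}), frozenset({0, 1})])


@pytest.fixture
def h3_partitioned(h3):
    """{0,1} in category 1, {0,1,2} in category 2."""
    return PartitionedHypergraph(base=h3, category_of=[2, 1], K=2)


@pytest.fixture
def single_edge():
    return Hypergraph(2, [frozenset({0, 1})])


def small_instances(max_n=12, n_instances=8, seed0=100):
    """Seeded random hypergraphs with n <= max_n for brute-force oracles."""
    out = []
    for k in range(n_instances):
        rng = np.random.default_rng(seed0 + k)
        n = int(rng.integers(5, max_n + 1))
        counts = {2: int(rng.integers(2, n)), 3: int(rng.integers(1, 4))}
        if n >= 4 and rng.random() < 0.5:
            counts[4] = 1
        out.append(random_hypergraph(n, counts, seed0 + 1000 + k))
    return out


@pytest.fixture(scope="session")
def brute_instances():
    return small_instances()
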