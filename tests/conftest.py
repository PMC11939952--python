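import numpy as np
import pytest

from csnn.topology import NetworkTopology


def build_topology(n, edges, weights=None, kinds=None, delays=None, directions=None):
    """Hand-built topology for unit tests (bypasses the generator)."""
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    e = len(edges)
    return NetworkTopology(
        n_nodes=n,
        edges=edges,
        weight=np.ones(e) if weights is None else np.asarray(weights, float),
        node_kind=np.array(["E"] * n if kinds is None else list(kinds), dtype="U1"),
        delay_ms=np.full(e, 1.0) if delays is None else np.asarray(delays, float),
        direction=np.zeros(e, dtype=np.int64) if directions is None else np.asarray(directions),
    )


@pytest.fixture
def triangle():
    return build_topology(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def star5():
    return build_topology(5, [(0, i) for i in range(1, 5)])


def random_connected_topology(rng, n_max=8):
    """Random small connected weighted graph for oracle comparisons."""
    n = int(rng.integers(3, n_max + 1))
    # random spanning tree guarantees connectivity
    edges = {(min(i, int(rng.integers(0, i))), i) for i in range(1, n)}
    n_extra = int(rng.integers(0, n))
    for _ in range(n_extra):
        u, v = rng.choice(n, size=2, replace=False)
        edges.add((min(u, v), max(u, v)))
    edges = sorted(edges)
    weights = rng.uniform(0.2, 5.0, size=len(edges))
    return build_topology(n, edges, weights=weights)
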