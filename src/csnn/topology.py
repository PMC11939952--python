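"""Weighted complex-network topologies with small-world and scale-free character.

The generator grows a weighted network by strength-preferential attachment
with local weight reinforcement (the Barrat–Barthelemy–Vespignani mechanism)
and then perturbs it with probabilistic edge reconnection, so that a single
parameter ``pn`` tunes the balance between scale-free heterogeneity and
small-world randomness.  The module also implements the weighted graph
metrics used to judge biological plausibility of the result: the mean
weighted clustering coefficient, the mean weighted shortest path length
(edge length = reciprocal weight), the fitted power-law exponent of the
degree distribution, and the small-world coefficient against Erdős–Rényi
references.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "NetworkTopology",
    "TopologyMetrics",
    "generate_bbv",
    "weighted_clustering",
    "weighted_spl",
    "fit_gamma",
    "small_world_sigma",
]

#: inclusive bounds (ms) for synaptic transmission delays
DELAY_RANGE_MS = (0.1, 40.0)
#: excitatory fraction of the population
EXCITATORY_FRACTION = 0.8


@dataclass
class NetworkTopology:
    """A connected, weighted, undirected graph with synapse annotations.

    Edges are stored once as unordered pairs ``(u, v)``; ``direction`` marks
    which endpoint acts presynaptically when the edge is instantiated as a
    synapse (0 means ``u -> v``, 1 means ``v -> u``).  ``weight`` holds the
    generation-time (topological) weights used by the graph metrics; the
    simulation engine rescales them to the synaptic conductance range.

    Attributes
    ----------
    n_nodes : int
        Number of nodes ``N``.
    edges : ndarray of shape (E, 2)
        Unordered node pairs, no self-loops, no duplicates.
    weight : ndarray of shape (E,)
        Positive topological edge weights.
    node_kind : ndarray of shape (N,)
        ``"E"`` (excitatory) or ``"I"`` (inhibitory) per node, at a 4:1 ratio.
    delay_ms : ndarray of shape (E,)
        Transmission delay per edge, uniform on [0.1, 40] ms.
    direction : ndarray of shape (E,)
        0 or 1; presynaptic endpoint selector.
    """

    n_nodes: int
    edges: np.ndarray
    weight: np.ndarray
    node_kind: np.ndarray
    delay_ms: np.ndarray
    direction: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.weight = np.asarray(self.weight, dtype=float)
        self.node_kind = np.asarray(self.node_kind, dtype="U1")
        self.delay_ms = np.asarray(self.delay_ms, dtype=float)
        self.direction = np.asarray(self.direction, dtype=np.int64)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on breach."""
        n, e = self.n_nodes, len(self.edges)
        if not (len(self.weight) == len(self.delay_ms) == len(self.direction) == e):
            raise ValueError("edge attribute arrays disagree in length")
        if len(self.node_kind) != n:
            raise ValueError("node_kind length != n_nodes")
        if e:
            if (self.edges[:, 0] == self.edges[:, 1]).any():
                raise ValueError("self-loops are not allowed")
            if self.edges.min() < 0 or self.edges.max() >= n:
                raise ValueError("edge endpoint out of range")
            key = np.sort(self.edges, axis=1)
            if len(np.unique(key, axis=0)) != e:
                raise ValueError("duplicate edges")
            if (self.weight <= 0).any():
                raise ValueError("all topological weights must be positive")
            lo, hi = DELAY_RANGE_MS
            if (self.delay_ms < lo).any() or (self.delay_ms > hi).any():
                raise ValueError(f"delays must lie in [{lo}, {hi}] ms")
        if not np.isin(self.node_kind, ["E", "I"]).all():
            raise ValueError("node_kind entries must be 'E' or 'I'")
        if nx.number_connected_components(self.to_networkx()) != 1:
            raise ValueError("topology must be a single connected component")

    # -- views -----------------------------------------------------------
    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def pre(self) -> np.ndarray:
        """Presynaptic endpoint of each edge."""
        return np.where(self.direction == 0, self.edges[:, 0], self.edges[:, 1])

    @property
    def post(self) -> np.ndarray:
        """Postsynaptic endpoint of each edge."""
        return np.where(self.direction == 0, self.edges[:, 1], self.edges[:, 0])

    def weight_matrix(self) -> np.ndarray:
        """Dense symmetric weight matrix of the undirected view."""
        w = np.zeros((self.n_nodes, self.n_nodes))
        u, v = self.edges[:, 0], self.edges[:, 1]
        w[u, v] = self.weight
        w[v, u] = self.weight
        return w

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(
            (int(u), int(v), float(w)) for (u, v), w in zip(self.edges, self.weight)
        )
        return g

    # -- serialization ---------------------------------------------------
    def to_csv(self, edge_path, node_path) -> None:
        """Write edge and node tables; round-trips exactly via repr floats."""
        pd.DataFrame(
            {
                "source": self.edges[:, 0],
                "target": self.edges[:, 1],
                "weight": self.weight,
                "delay_ms": self.delay_ms,
                "direction": self.direction,
            }
        ).to_csv(edge_path, index=False, float_format="%.17g")
        pd.DataFrame(
            {"node_id": np.arange(self.n_nodes), "kind": self.node_kind}
        ).to_csv(node_path, index=False)

    @classmethod
    def from_csv(cls, edge_path, node_path) -> "NetworkTopology":
        e = pd.read_csv(edge_path, float_precision="round_trip")
        nodes = pd.read_csv(node_path)
        return cls(
            n_nodes=len(nodes),
            edges=e[["source", "target"]].to_numpy(),
            weight=e["weight"].to_numpy(),
            node_kind=nodes["kind"].to_numpy(),
            delay_ms=e["delay_ms"].to_numpy(),
            direction=e["direction"].to_numpy(),
        )


@dataclass
class TopologyMetrics:
    """Scale-free / small-world summary of one topology."""

    gamma: float
    sigma: float
    weighted_cc: float
    weighted_spl: float


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _pa_pick(rng, strength, n_existing, exclude):
    """Strength-preferential pick among nodes [0, n_existing) not in exclude."""
    s = strength[:n_existing].copy()
    s[[i for i in exclude if i < n_existing]] = 0.0
    total = s.sum()
    if total <= 0:  # degenerate: fall back to uniform over allowed nodes
        allowed = [i for i in range(n_existing) if i not in exclude]
        return int(rng.choice(allowed))
    return int(rng.choice(n_existing, p=s / total))


def generate_bbv(
    n_nodes: int,
    pn: float,
    m_edges: int = 20,
    w0: float = 0.52,
    delta: float = 0.052,
    seed: int | None = None,
    rewire_strategy: str = "growth_and_rewire",
) -> NetworkTopology:
    """Grow a weighted network by strength-preferential attachment and rewire it.

    Growth starts from a complete clique of ``m_edges + 1`` nodes with all
    weights ``w0``.  Each incoming node attaches ``m_edges`` edges of weight
    ``w0`` to distinct existing nodes chosen with probability proportional to
    node strength ``s_i``; every attachment to node ``i`` reinforces ``i``'s
    pre-existing edges by ``delta * w_ij / s_i`` (local weight plasticity).
    The reconnection probability ``pn`` then randomizes the outcome:

    ``rewire_strategy="growth_and_rewire"`` (default)
        during growth each attachment is made to a uniformly random node with
        probability ``pn`` instead of preferentially, and after growth each
        edge independently keeps one endpoint and moves the other to a
        uniformly random non-adjacent node with probability ``pn``
        (Watts–Strogatz-style; connectivity is repaired deterministically).
    ``rewire_strategy="rewire_post"``
        preferential growth only, followed by the WS-style rewiring pass.
    ``rewire_strategy="during_growth"``
        random-vs-preferential mixing during growth only, no rewiring pass.

    Node kinds are assigned excitatory:inhibitory at 4:1 uniformly at random,
    transmission delays uniformly on [0.1, 40] ms, and each undirected edge
    receives a fair-coin synaptic direction.

    Parameters
    ----------
    n_nodes : int
        Final network size; must satisfy ``n_nodes >= m_edges + 1`` and >= 3.
    pn : float
        Reconnection probability in [0, 1].
    m_edges : int
        Edges attached per incoming node.
    w0, delta : float
        Initial edge weight and reinforcement increment; only their ratio
        shapes the degree distribution, the product scale sets the weighted
        path lengths.
    seed : int, optional
        Seed for bit-reproducible generation.
    """
    if n_nodes < 3:
        raise ValueError("n_nodes must be at least 3")
    if n_nodes < m_edges + 1:
        raise ValueError("n_nodes must be at least m_edges + 1")
    if not 0.0 <= pn <= 1.0:
        raise ValueError("pn must lie in [0, 1]")
    if w0 <= 0 or delta <= 0:
        raise ValueError("w0 and delta must be positive")
    if rewire_strategy not in ("growth_and_rewire", "rewire_post", "during_growth"):
        raise ValueError(f"unknown rewire_strategy: {rewire_strategy!r}")
    mix_during = rewire_strategy in ("growth_and_rewire", "during_growth")
    rewire_after = rewire_strategy in ("growth_and_rewire", "rewire_post")

    rng = np.random.default_rng(seed)
    n, m = int(n_nodes), int(m_edges)
    adj: list[dict[int, float]] = [dict() for _ in range(n)]
    strength = np.zeros(n)

    def add_edge(u, v, w):
        adj[u][v] = w
        adj[v][u] = w
        strength[u] += w
        strength[v] += w

    # seed clique
    m0 = m + 1
    for i in range(m0):
        for j in range(i + 1, m0):
            add_edge(i, j, w0)

    for v in range(m0, n):
        chosen: set[int] = set()
        for _ in range(m):
            if mix_during and rng.random() < pn:
                allowed = [i for i in range(v) if i not in chosen]
                target = int(rng.choice(allowed))
            else:
                target = _pa_pick(rng, strength, v, chosen | {v})
            chosen.add(target)
            # BBV local reinforcement of the target's existing edges
            s_old = strength[target]
            if s_old > 0 and delta > 0:
                for j, w in list(adj[target].items()):
                    inc = delta * w / s_old
                    adj[target][j] = w + inc
                    adj[j][target] = w + inc
                    strength[target] += inc
                    strength[j] += inc
            add_edge(v, target, w0)

    if rewire_after and pn > 0:
        _rewire_in_place(adj, strength, n, pn, rng)

    # flatten undirected adjacency into an edge table
    e_u, e_v, e_w = [], [], []
    for u in range(n):
        for v, w in adj[u].items():
            if u < v:
                e_u.append(u)
                e_v.append(v)
                e_w.append(w)
    edges = np.column_stack([e_u, e_v])
    weight = np.array(e_w)

    n_exc = int(round(EXCITATORY_FRACTION * n))
    kinds = np.array(["I"] * n, dtype="U1")
    kinds[rng.choice(n, size=n_exc, replace=False)] = "E"

    lo, hi = DELAY_RANGE_MS
    delays = rng.uniform(lo, hi, size=len(edges))
    direction = rng.integers(0, 2, size=len(edges))

    return NetworkTopology(
        n_nodes=n,
        edges=edges,
        weight=weight,
        node_kind=kinds,
        delay_ms=delays,
        direction=direction,
        meta={
            "pn": pn,
            "m_edges": m,
            "w0": w0,
            "delta": delta,
            "seed": seed,
            "rewire_strategy": rewire_strategy,
        },
    )


def _move_endpoint(adj, strength, u, v, new_v):
    """Replace edge (u, v) by (u, new_v), keeping its weight."""
    w = adj[u].pop(v)
    del adj[v][u]
    strength[v] -= w
    adj[u][new_v] = w
    adj[new_v][u] = w
    strength[new_v] += w


def _rewire_in_place(adj, strength, n, pn, rng):
    """WS-style endpoint rewiring of every edge with probability pn.

    Each selected edge keeps its ``u`` endpoint and weight and moves its
    ``v`` endpoint to a uniformly random node not already adjacent to ``u``.
    If the pass disconnects the graph, connectivity is repaired by moving
    one endpoint of a random giant-component edge into each stranded
    component (edge count and weights preserved).
    """
    edge_list = [(u, v) for u in range(n) for v in adj[u] if u < v]
    for u, v in edge_list:
        if rng.random() >= pn:
            continue
        if v not in adj[u]:  # already moved by an earlier rewire
            continue
        candidates = [x for x in range(n) if x != u and x not in adj[u]]
        if not candidates:
            continue
        _move_endpoint(adj, strength, u, v, int(rng.choice(candidates)))

    g = nx.Graph((u, v) for u in range(n) for v in adj[u])
    g.add_nodes_from(range(n))
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    while len(comps) > 1:
        giant, small = comps[0], comps[1]
        target = int(rng.choice(sorted(small)))
        # pick a giant edge whose removal keeps its endpoints connected
        giant_edges = [
            (u, v) for u in sorted(giant) for v in adj[u] if u < v and v in giant
        ]
        order = rng.permutation(len(giant_edges))
        for idx in order:
            u, v = giant_edges[idx]
            if target in adj[u] or len(adj[v]) < 2:
                continue
            _move_endpoint(adj, strength, u, v, target)
            break
        else:  # pragma: no cover - pathological density
            raise RuntimeError("could not repair connectivity after rewiring")
        g = nx.Graph((a, b) for a in range(n) for b in adj[a])
        g.add_nodes_from(range(n))
        comps = sorted(nx.connected_components(g), key=len, reverse=True)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def weighted_clustering(topology: NetworkTopology) -> float:
    """Mean weighted clustering coefficient (Barrat form).

    For each node ``i`` with degree ``k_i >= 2`` and strength ``s_i``,

        C_i = 1 / (s_i (k_i - 1)) * sum_{j,h} (w_ij + w_ih)/2 * a_ij a_ih a_jh

    summed over ordered neighbor pairs; nodes with ``k_i < 2`` contribute 0.
    The value is invariant under a global rescaling of the weights and equals
    the unweighted clustering coefficient when all weights are equal.
    """
    n = topology.n_nodes
    if n == 0 or topology.n_edges == 0:
        raise ValueError("weighted clustering undefined on an empty graph")
    w = topology.weight_matrix()
    a = (w > 0).astype(float)
    deg = a.sum(axis=1)
    s = w.sum(axis=1)
    # sum over ordered (j, h): sum_h (sum_j w_ij a_jh) a_ih
    tri = ((w @ a) * a).sum(axis=1)
    c = np.zeros(n)
    mask = deg >= 2
    c[mask] = tri[mask] / (s[mask] * (deg[mask] - 1))
    return float(c.mean())


def weighted_spl(topology: NetworkTopology) -> float:
    """Mean weighted shortest path length with edge length ``1/w``.

    Averages the shortest-path distance over all ordered node pairs; a higher
    weight means a shorter effective distance.  Raises on disconnected input,
    naming the number of unreachable pairs.
    """
    n = topology.n_nodes
    if n < 2:
        raise ValueError("need at least two nodes for path lengths")
    u, v = topology.edges[:, 0], topology.edges[:, 1]
    lengths = 1.0 / topology.weight
    g = csr_matrix(
        (np.r_[lengths, lengths], (np.r_[u, v], np.r_[v, u])), shape=(n, n)
    )
    d = shortest_path(g, method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    n_unreachable = int(np.isinf(d[off]).sum())
    if n_unreachable:
        raise ValueError(
            f"graph is disconnected: {n_unreachable} ordered node pairs unreachable"
        )
    return float(d[off].mean())


def fit_gamma(topology: NetworkTopology, method: str = "mle") -> float:
    """Power-law exponent of the degree distribution.

    ``method="mle"`` (default) uses the discrete maximum-likelihood
    estimator ``gamma = 1 + n / sum(log(k_i / (kmin - 1/2)))`` with ``kmin``
    the smallest degree >= 2, the standard continuous approximation to the
    discrete Clauset estimator.  ``method="lsq"`` fits a least-squares line
    to the log-log CCDF instead.  Deterministic given the topology.
    """
    deg = topology.degrees()
    if len(np.unique(deg)) < 3:
        raise ValueError("degree sequence needs at least 3 distinct values")
    kmin = int(deg[deg >= 2].min())
    k = deg[deg >= kmin].astype(float)
    if method == "mle":
        return float(1.0 + len(k) / np.log(k / (kmin - 0.5)).sum())
    if method == "lsq":
        ks = np.sort(k)
        uniq, counts = np.unique(ks, return_counts=True)
        ccdf = 1.0 - np.cumsum(counts) / len(ks) + counts / len(ks)
        good = ccdf > 0
        slope = np.polyfit(np.log(uniq[good]), np.log(ccdf[good]), 1)[0]
        return float(1.0 - slope)
    raise ValueError(f"unknown method: {method!r}")


def _unweighted_c_and_l(g: nx.Graph) -> tuple[float, float]:
    c = nx.average_clustering(g)
    n = g.number_of_nodes()
    rows = sorted(g.nodes())
    a = nx.to_scipy_sparse_array(g, nodelist=rows, format="csr")
    d = shortest_path(a, method="D", directed=False, unweighted=True)
    off = ~np.eye(n, dtype=bool)
    if np.isinf(d[off]).any():
        raise ValueError("graph is disconnected")
    return float(c), float(d[off].mean())


def small_world_sigma(
    topology: NetworkTopology, n_random: int = 20, seed: int | None = None
) -> float:
    """Small-world coefficient sigma = (C/C_rand) / (L/L_rand), unweighted view.

    ``C_rand`` and ``L_rand`` are means over ``n_random`` connected
    Erdős–Rényi G(n, m) graphs matched on node and edge count.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    g = topology.to_networkx()
    c, length = _unweighted_c_and_l(g)
    n, e = g.number_of_nodes(), g.number_of_edges()
    rng = np.random.default_rng(seed)
    c_rand, l_rand = [], []
    for _ in range(n_random):
        for _ in range(200):
            ref = nx.gnm_random_graph(n, e, seed=int(rng.integers(2**31)))
            if nx.is_connected(ref):
                break
        else:
            raise RuntimeError("could not draw a connected reference graph")
        cr, lr = _unweighted_c_and_l(ref)
        c_rand.append(cr)
        l_rand.append(lr)
    c_rand_m = float(np.mean(c_rand))
    l_rand_m = float(np.mean(l_rand))
    if c_rand_m == 0:
        raise ValueError("reference clustering is zero; sigma undefined")
    return float((c / c_rand_m) / (length / l_rand_m))


def topology_metrics(
    topology: NetworkTopology, n_random: int = 20, seed: int | None = None
) -> TopologyMetrics:
    """Convenience bundle of all four metrics for one topology."""
    return TopologyMetrics(
        gamma=fit_gamma(topology),
        sigma=small_world_sigma(topology, n_random=n_random, seed=seed),
        weighted_cc=weighted_clustering(topology),
        weighted_spl=weighted_spl(topology),
    )
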