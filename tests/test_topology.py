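"""Topology generation and weighted graph metrics."""

from types import SimpleNamespace

import networkx as nx
import numpy as np
import pytest

from csnn.topology import (
    NetworkTopology,
    fit_gamma,
    generate_bbv,
    small_world_sigma,
    weighted_clustering,
    weighted_spl,
)

from conftest import build_topology, random_connected_topology


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_weighted_clustering(topo):
    """Triple enumeration of the weighted clustering formula."""
    w = topo.weight_matrix()
    a = (w > 0).astype(int)
    n = topo.n_nodes
    total = 0.0
    for i in range(n):
        k = a[i].sum()
        s = w[i].sum()
        if k < 2:
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                acc += (w[i, j] + w[i, h]) / 2.0 * a[i, j] * a[i, h] * a[j, h]
        total += acc / (s * (k - 1))
    return total / n


def brute_weighted_spl(topo):
    """Floyd–Warshall on 1/w edge lengths."""
    n = topo.n_nodes
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for (u, v), w in zip(topo.edges, topo.weight):
        d[u, v] = d[v, u] = 1.0 / w
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    off = ~np.eye(n, dtype=bool)
    return d[off].mean()


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

class TestGenerateBBV:
    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            generate_bbv(2, 0.3)
        with pytest.raises(ValueError):
            generate_bbv(10, 1.5)
        with pytest.raises(ValueError):
            generate_bbv(10, 0.3, w0=-1.0)
        with pytest.raises(ValueError):
            generate_bbv(10, 0.3, m_edges=12)
        with pytest.raises(ValueError):
            generate_bbv(10, 0.3, m_edges=3, rewire_strategy="bogus")

    def test_seed_clique_only(self):
        """n_nodes = m+1 yields the complete seed clique with all weights w0."""
        topo = generate_bbv(4, 0.0, m_edges=3, w0=2.5, delta=1.0, seed=0)
        assert topo.n_edges == 6
        assert np.allclose(topo.weight, 2.5)

    def test_structural_invariants(self):
        topo = generate_bbv(80, 0.3, m_edges=4, seed=3)
        topo.validate()  # no self loops, duplicates, connectivity, delays
        deg = topo.degrees()
        assert deg.min() >= 1
        n_exc = (topo.node_kind == "E").sum()
        assert n_exc == round(0.8 * 80)
        assert topo.delay_ms.min() >= 0.1 and topo.delay_ms.max() <= 40.0

    def test_bit_reproducible(self):
        a = generate_bbv(60, 0.4, m_edges=3, seed=11)
        b = generate_bbv(60, 0.4, m_edges=3, seed=11)
        assert np.array_equal(a.edges, b.edges)
        assert np.array_equal(a.weight, b.weight)
        assert np.array_equal(a.delay_ms, b.delay_ms)
        assert np.array_equal(a.node_kind, b.node_kind)
        c = generate_bbv(60, 0.4, m_edges=3, seed=12)
        assert not np.array_equal(a.edges, c.edges) or not np.array_equal(
            a.weight, c.weight
        )

    def test_preferential_attachment_frequencies(self):
        """With pn=0, attachment follows strength-proportional probabilities.

        Hand-derived oracle for n=4, m=1, w0=delta=1: the seed pair is
        {0, 1} with one edge of weight 1.  Node 2 picks either (uniform by
        symmetry); the pick X has its existing edge reinforced to weight 2
        (delta * w/s = 1), then gains the new edge, so strengths become
        s_X=3, s_Y=2, s_2=1.  Node 3's attachment probabilities are
        therefore 1/2 (node 2's target), 1/3 (the other seed), 1/6 (node 2).
        """
        n_trials = 4000
        hits_same = hits_new = 0
        for seed in range(n_trials):
            topo = generate_bbv(4, 0.0, m_edges=1, w0=1.0, delta=1.0, seed=seed)
            nbr = {}
            for u, v in topo.edges:
                nbr.setdefault(u, set()).add(v)
                nbr.setdefault(v, set()).add(u)
            target2 = next(iter(nbr[2] - {3}))
            target3 = next(iter(nbr[3]))
            hits_same += target3 == target2
            hits_new += target3 == 2
        se = np.sqrt(0.5 * 0.5 / n_trials)
        assert hits_same / n_trials == pytest.approx(1 / 2, abs=5 * se)
        assert hits_new / n_trials == pytest.approx(1 / 6, abs=5 * se)

    def test_scale_free_tail_at_pn_zero(self):
        """Pure growth (pn=0): log-log CCDF slope agrees with the MLE fit."""
        topo = generate_bbv(500, 0.0, seed=2)
        g_mle = fit_gamma(topo, method="mle")
        g_lsq = fit_gamma(topo, method="lsq")
        assert g_mle > 1.0
        assert abs(g_lsq - g_mle) < 0.5

    def test_weight_scale_invariance(self):
        """Scaling (w0, delta) jointly rescales weights, leaves structure."""
        a = generate_bbv(60, 0.3, m_edges=3, w0=1.0, delta=0.1, seed=5)
        b = generate_bbv(60, 0.3, m_edges=3, w0=2.0, delta=0.2, seed=5)
        assert np.array_equal(a.edges, b.edges)
        assert np.allclose(b.weight, 2.0 * a.weight)

    def test_roundtrip_csv(self, tmp_path):
        topo = generate_bbv(40, 0.3, m_edges=3, seed=7)
        topo.to_csv(tmp_path / "e.csv", tmp_path / "n.csv")
        back = NetworkTopology.from_csv(tmp_path / "e.csv", tmp_path / "n.csv")
        assert np.array_equal(topo.edges, back.edges)
        assert np.array_equal(topo.weight, back.weight)
        assert np.array_equal(topo.delay_ms, back.delay_ms)
        assert np.array_equal(topo.direction, back.direction)
        assert np.array_equal(topo.node_kind, back.node_kind)


# ---------------------------------------------------------------------------
# weighted clustering coefficient
# ---------------------------------------------------------------------------

class TestWeightedClustering:
    def test_triangle_equal_weights(self, triangle):
        assert weighted_clustering(triangle) == pytest.approx(1.0)

    def test_star_has_no_triangles(self, star5):
        assert weighted_clustering(star5) == pytest.approx(0.0)

    def test_four_node_hand_case(self):
        topo = build_topology(
            4, [(0, 1), (0, 2), (1, 2), (2, 3)], weights=[1.0, 2.0, 3.0, 4.0]
        )
        assert weighted_clustering(topo) == pytest.approx(
            brute_weighted_clustering(topo)
        )

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            weighted_clustering(build_topology(3, np.empty((0, 2))))

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            topo = random_connected_topology(rng)
            assert weighted_clustering(topo) == pytest.approx(
                brute_weighted_clustering(topo), rel=1e-10
            )

    def test_scale_invariant(self):
        rng = np.random.default_rng(1)
        topo = random_connected_topology(rng)
        scaled = build_topology(
            topo.n_nodes, topo.edges, weights=topo.weight * 7.5
        )
        assert weighted_clustering(topo) == pytest.approx(
            weighted_clustering(scaled)
        )


# ---------------------------------------------------------------------------
# weighted shortest path length
# ---------------------------------------------------------------------------

class TestWeightedSPL:
    def test_two_nodes(self):
        topo = build_topology(2, [(0, 1)], weights=[4.0])
        assert weighted_spl(topo) == pytest.approx(0.25)

    def test_path_graph_hand_value(self):
        topo = build_topology(3, [(0, 1), (1, 2)], weights=[1.0, 1.0])
        assert weighted_spl(topo) == pytest.approx(4.0 / 3.0)

    def test_matches_floyd_warshall(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            topo = random_connected_topology(rng, n_max=10)
            assert weighted_spl(topo) == pytest.approx(
                brute_weighted_spl(topo), rel=1e-10
            )

    def test_disconnected_graph_names_pair_count(self):
        topo = NetworkTopology.__new__(NetworkTopology)  # bypass validation
        topo.n_nodes = 4
        topo.edges = np.array([[0, 1], [2, 3]])
        topo.weight = np.array([1.0, 1.0])
        with pytest.raises(ValueError, match="8 ordered"):
            weighted_spl(topo)


# ---------------------------------------------------------------------------
# power-law exponent
# ---------------------------------------------------------------------------

class TestFitGamma:
    def test_recovers_synthetic_exponent(self):
        """Degrees sampled from P(k) ~ k^-2.5 recover gamma within 0.1."""
        rng = np.random.default_rng(0)
        u = rng.random(100_000)
        kmin = 3
        deg = np.floor((kmin - 0.5) * (1 - u) ** (-1 / 1.5) + 0.5).astype(int)
        stub = SimpleNamespace(degrees=lambda: deg)
        assert fit_gamma(stub) == pytest.approx(2.5, abs=0.1)

    def test_regular_graph_rejected(self):
        clique = generate_bbv(4, 0.0, m_edges=3, seed=0)
        with pytest.raises(ValueError):
            fit_gamma(clique)

    def test_deterministic(self):
        topo = generate_bbv(200, 0.3, m_edges=5, seed=9)
        assert fit_gamma(topo) == fit_gamma(topo)


# ---------------------------------------------------------------------------
# small-world coefficient
# ---------------------------------------------------------------------------

def _wrap_nx(g):
    edges = np.array(sorted(tuple(sorted(e)) for e in g.edges()))
    return build_topology(g.number_of_nodes(), edges)


class TestSmallWorldSigma:
    def test_er_graph_near_one(self):
        g = nx.gnm_random_graph(200, 1200, seed=1)
        assert nx.is_connected(g)
        sigma = small_world_sigma(_wrap_nx(g), n_random=10, seed=4)
        assert 0.7 < sigma < 1.3

    def test_watts_strogatz_exceeds_one(self):
        g = nx.connected_watts_strogatz_graph(150, 8, 0.05, seed=2)
        sigma = small_world_sigma(_wrap_nx(g), n_random=10, seed=4)
        assert sigma > 1.5

    def test_requires_positive_n_random(self, triangle):
        with pytest.raises(ValueError):
            small_world_sigma(triangle, n_random=0)

    def test_sigma_declines_toward_full_reconnection(self):
        """Randomizing away the growth structure pulls sigma toward 1."""
        lo = np.mean(
            [
                small_world_sigma(
                    generate_bbv(300, 0.3, seed=s), n_random=5, seed=100 + s
                )
                for s in range(3)
            ]
        )
        hi = np.mean(
            [
                small_world_sigma(
                    generate_bbv(300, 1.0, seed=s), n_random=5, seed=100 + s
                )
                for s in range(3)
            ]
        )
        assert lo > hi > 0.9
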