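"""k-core, MCODE vertex weighting, expansion and scoring against oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

import lactylome as lm
from lactylome.network import density


def kcore_oracle(graph, k):
    """Union of all node subsets whose induced subgraph has min degree >= k
    (exponential brute force; the k-core is the maximal such subset)."""
    nodes = list(graph.nodes)
    core: set = set()
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            sub = graph.subgraph(subset)
            if all(d >= k for _, d in sub.degree):
                core |= set(subset)
    return core


def vertex_weight_oracle(graph, v):
    """MCODE weight recomputed through the exponential k-core oracle."""
    closed = set(graph.neighbors(v)) | {v}
    sub = graph.subgraph(closed)
    if sub.number_of_edges() == 0:
        return 0.0
    for k in range(len(closed), 0, -1):
        members = kcore_oracle(sub, k)
        if members:
            return k * density(graph.subgraph(members))
    return 0.0


def two_cliques_with_linker():
    """Two K6 cliques joined through a single low-weight linker node."""
    g = nx.Graph()
    for prefix in ("a", "b"):
        members = [f"{prefix}{i}" for i in range(6)]
        g.add_edges_from(itertools.combinations(members, 2))
    g.add_edge("a0", "link")
    g.add_edge("link", "b0")
    return g


def random_small_graphs(seed, n_graphs=60, max_nodes=6):
    rng = np.random.default_rng(seed)
    for _ in range(n_graphs):
        n = int(rng.integers(2, max_nodes + 1))
        p = float(rng.uniform(0.1, 0.9))
        yield nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))


class TestKCore:
    def test_triangle_is_its_own_2core(self):
        tri = nx.complete_graph(3)
        assert set(lm.k_core(tri, 2).nodes) == set(tri.nodes)

    def test_star_has_empty_2core(self):
        star = nx.star_graph(3)
        assert lm.k_core(star, 2).number_of_nodes() == 0

    def test_k0_is_identity(self):
        g = nx.gnp_random_graph(8, 0.3, seed=1)
        assert set(lm.k_core(g, 0).nodes) == set(g.nodes)

    def test_idempotent(self):
        g = nx.gnp_random_graph(10, 0.4, seed=2)
        once = lm.k_core(g, 2)
        twice = lm.k_core(once, 2)
        assert set(once.nodes) == set(twice.nodes)

    def test_matches_bruteforce_on_small_graphs(self):
        for g in random_small_graphs(5):
            for k in range(0, 4):
                got = set(lm.k_core(g, k).nodes)
                want = kcore_oracle(g, k) if k > 0 else set(g.nodes)
                assert got == want


class TestVertexWeights:
    def test_k4_all_weights_three(self):
        weights = lm.vertex_weights(nx.complete_graph(4))
        assert all(np.isclose(w, 3.0) for w in weights.values())

    def test_isolated_node_zero(self):
        g = nx.Graph()
        g.add_node("x")
        assert lm.vertex_weights(g)["x"] == 0.0

    def test_path_middle_node(self):
        weights = lm.vertex_weights(nx.path_graph(3))
        assert np.isclose(weights[1], 2 / 3)

    def test_matches_bruteforce_on_small_graphs(self):
        for g in random_small_graphs(7):
            weights = lm.vertex_weights(g)
            for v in g.nodes:
                assert np.isclose(weights[v], vertex_weight_oracle(g, v))

    def test_adding_edge_never_decreases_core_order(self):
        """The core-order factor of the weight is edge-monotone (the density
        factor is not: an extra edge can pull low-degree nodes into the top
        core and dilute it, see the companion counterexample)."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            g = nx.gnp_random_graph(7, 0.4, seed=int(rng.integers(2**31)))
            non_edges = list(nx.non_edges(g))
            if not non_edges:
                continue
            u, v = non_edges[int(rng.integers(len(non_edges)))]
            before = {n: max(nx.core_number(g.subgraph(set(g[n]) | {n})).values(),
                             default=0) for n in g}
            g.add_edge(u, v)
            after = {n: max(nx.core_number(g.subgraph(set(g[n]) | {n})).values(),
                            default=0) for n in g}
            assert all(after[n] >= before[n] for n in before)

    def test_weight_can_decrease_when_top_core_dilutes(self):
        # triangle v-a-b plus pendant d on v: weight(v) = 2 x 1 = 2
        g = nx.Graph([("v", "a"), ("v", "b"), ("a", "b"), ("v", "d")])
        assert np.isclose(lm.vertex_weights(g)["v"], 2.0)
        # edge a-d enlarges v's 2-core to 4 nodes / 5 edges: 2 x 5/6 < 2
        g.add_edge("a", "d")
        assert np.isclose(lm.vertex_weights(g)["v"], 2 * 5 / 6)


class TestClusterScore:
    @pytest.mark.parametrize("builder,expected", [
        (lambda: nx.complete_graph(4), 4.0),
        (lambda: nx.complete_graph(3), 3.0),
        (lambda: nx.path_graph(4), 2.0),  # density 1/2 x 4 nodes
    ])
    def test_known_scores(self, builder, expected):
        g = builder()
        assert np.isclose(lm.cluster_score(g, set(g.nodes)), expected)

    def test_single_member_rejected(self):
        with pytest.raises(ValueError):
            lm.cluster_score(nx.complete_graph(3), {0})


class TestMcodeFindComplexes:
    def test_two_planted_k6_cliques(self):
        clusters = lm.mcode_find_complexes(two_cliques_with_linker())
        assert len(clusters) == 2
        assert all(np.isclose(c.score, 6.0) for c in clusters)
        memberships = sorted(tuple(sorted(c.members)) for c in clusters)
        assert memberships == [tuple(f"a{i}" for i in range(6)),
                               tuple(f"b{i}" for i in range(6))]

    def test_direct_bridge_merges_cliques(self):
        """A direct bridge edge between two K6 cliques leaves every node at
        weight 5, so seeded expansion hops the bridge: one merged cluster
        (published-algorithm behaviour, frozen here)."""
        g = nx.Graph()
        for prefix in ("a", "b"):
            members = [f"{prefix}{i}" for i in range(6)]
            g.add_edges_from(itertools.combinations(members, 2))
        g.add_edge("a0", "b0")
        clusters = lm.mcode_find_complexes(g)
        assert len(clusters) == 1 and len(clusters[0].members) == 12

    def test_edgeless_graph_no_clusters(self):
        g = nx.empty_graph(5)
        assert lm.mcode_find_complexes(g) == []

    def test_single_k4(self):
        clusters = lm.mcode_find_complexes(nx.complete_graph(4))
        assert len(clusters) == 1
        assert np.isclose(clusters[0].score, 4.0)

    def test_deterministic(self):
        g = lm.generate_ppi_graph(45, [(15, 0.9)] * 3, p_out=0.02, seed=17)
        a = lm.mcode_find_complexes(g)
        b = lm.mcode_find_complexes(g)
        assert [(c.sorted_members(), c.score) for c in a] == \
               [(c.sorted_members(), c.score) for c in b]

    def test_planted_partition_recovery_without_bridges(self):
        """Dense planted blocks are recovered near-exactly when no
        between-block edges exist."""
        g = lm.generate_ppi_graph(45, [(15, 0.9)] * 3, p_out=0.0, seed=17)
        planted = nx.get_node_attributes(g, "planted")
        blocks = [set(n for n, b in planted.items() if b == i) for i in range(3)]
        clusters = lm.mcode_find_complexes(g)
        for block in blocks:
            best = max(len(block & set(c.members)) / len(block | set(c.members))
                       for c in clusters)
            assert best >= 0.8

    def test_between_block_edges_bleed_clusters(self):
        """With p_out = 0.02 the seeded expansion crosses bridge edges
        between equally-weighted dense blocks and merges them — the
        published algorithm's known bleeding behaviour, frozen here."""
        g = lm.generate_ppi_graph(45, [(15, 0.9)] * 3, p_out=0.02, seed=17)
        clusters = lm.mcode_find_complexes(g)
        assert max(len(c.members) for c in clusters) > 15

    def test_self_loops_rejected(self):
        g = nx.Graph([("a", "a"), ("a", "b")])
        with pytest.raises(ValueError):
            lm.mcode_find_complexes(g)
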