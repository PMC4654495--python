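"""Modularity evaluation, fast-greedy agglomeration and the resolution sweep."""

import numpy as np
import pytest

from termcommunities.community import (
    CommunityRegistry,
    Partition,
    WeightedGraph,
    community_size_summary,
    fast_greedy,
    modularity,
    resolution_sweep,
)

from _oracles import dense_modularity, exhaustive_best_modularity


def two_disjoint_edges():
    A = np.zeros((4, 4))
    A[0, 1] = A[1, 0] = 1.0
    A[2, 3] = A[3, 2] = 1.0
    return WeightedGraph.from_dense(A)


def two_cliques(k=4, bridge=1.0):
    n = 2 * k
    A = np.zeros((n, n))
    for block in (range(k), range(k, n)):
        for i in block:
            for j in block:
                if i != j:
                    A[i, j] = 1.0
    A[k - 1, k] = A[k, k - 1] = bridge
    return A


def random_weighted_graph(rng, n, n_edges):
    A = np.zeros((n, n))
    for _ in range(n_edges):
        i, j = rng.integers(0, n, size=2)
        if i != j and A[i, j] == 0:
            A[i, j] = A[j, i] = rng.random()
    return A


class TestModularity:
    def test_two_edges_partitioned_into_edges(self):
        g = two_disjoint_edges()
        p = {0: 0, 1: 0, 2: 1, 3: 1}
        assert modularity(g, p, r=0.0) == pytest.approx(0.5, abs=1e-15)

    def test_singletons_closed_form(self):
        rng = np.random.default_rng(1)
        A = random_weighted_graph(rng, 12, 30)
        g = WeightedGraph.from_dense(A)
        k = g.strengths
        two_m = k.sum()
        expected = -float(np.sum(k**2)) / two_m**2
        singletons = {i: i for i in range(g.n)}
        assert modularity(g, singletons, r=0.0) == pytest.approx(expected, abs=1e-12)

    def test_positive_resolution_strictly_lowers_q(self):
        g = two_disjoint_edges()
        p = {0: 0, 1: 0, 2: 1, 3: 1}
        assert modularity(g, p, r=1.5) < modularity(g, p, r=0.0)

    def test_matches_dense_matrix_evaluation(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            A = random_weighted_graph(rng, 15, 40)
            g = WeightedGraph.from_dense(A)
            labels = rng.integers(0, 4, size=g.n)
            r = float(rng.random() * 3)
            assert modularity(g, dict(enumerate(labels)), r) == pytest.approx(
                dense_modularity(A, labels, r), abs=1e-12)

    def test_incomplete_partition_rejected(self):
        g = two_disjoint_edges()
        with pytest.raises(ValueError):
            modularity(g, {0: 0, 1: 0}, r=0.0)

    def test_negative_resolution_rejected(self):
        g = two_disjoint_edges()
        with pytest.raises(ValueError):
            modularity(g, {i: 0 for i in range(4)}, r=-0.1)


class TestFastGreedy:
    def test_two_edges_cut_at_half(self):
        p, _ = fast_greedy(two_disjoint_edges(), r=0.0)
        assert p.Q == pytest.approx(0.5, abs=1e-15)
        assert p.n_communities == 2

    def test_two_cliques_recovered_and_match_exhaustive(self):
        A = two_cliques(4)
        p, _ = fast_greedy(WeightedGraph.from_dense(A), r=0.0)
        assert p.n_communities == 2
        assert {frozenset(c) for c in p.communities()} == {
            frozenset(range(4)), frozenset(range(4, 8))}
        assert p.Q == pytest.approx(exhaustive_best_modularity(A), abs=1e-12)

    def test_stored_q_equals_direct_reevaluation(self):
        rng = np.random.default_rng(3)
        for r in (0.0, 0.7, 4.0):
            A = random_weighted_graph(rng, 40, 140)
            g = WeightedGraph.from_dense(A)
            p, _ = fast_greedy(g, r=r)
            assert p.Q == pytest.approx(modularity(g, p, r=r), abs=1e-10)

    def test_every_merge_delta_matches_direct_reevaluation(self):
        rng = np.random.default_rng(9)
        A = random_weighted_graph(rng, 25, 70)
        g = WeightedGraph.from_dense(A)
        _, dendro = fast_greedy(g, r=1.2)
        parent = list(range(g.n))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        q_prev = dendro.q_initial
        assert q_prev == pytest.approx(
            modularity(g, {i: i for i in range(g.n)}, r=1.2), abs=1e-12)
        for step in dendro.merges:
            parent[step.b] = step.a
            labels = {i: find(i) for i in range(g.n)}
            q_direct = modularity(g, labels, r=1.2)
            assert step.q_after == pytest.approx(q_direct, abs=1e-10)
            assert step.delta_q == pytest.approx(q_direct - q_prev, abs=1e-10)
            q_prev = q_direct

    def test_greedy_never_beats_exhaustive_optimum(self):
        rng = np.random.default_rng(5)
        for _ in range(6):
            n = int(rng.integers(5, 9))
            A = random_weighted_graph(rng, n, 2 * n)
            g = WeightedGraph.from_dense(A)
            if not g.edges:
                continue
            p, _ = fast_greedy(g, r=0.0)
            assert p.Q <= exhaustive_best_modularity(A) + 1e-12

    def test_matches_igraph_weighted_cnm(self):
        igraph = pytest.importorskip("igraph")
        rng = np.random.default_rng(5)
        for _ in range(8):
            n = int(rng.integers(20, 80))
            A = random_weighted_graph(rng, n, 3 * n)
            g = WeightedGraph.from_dense(A)
            if not g.edges:
                continue
            p, _ = fast_greedy(g, r=0.0)
            gi = igraph.Graph.Weighted_Adjacency(
                A.tolist(), mode="undirected", attr="weight")
            clustering = gi.community_fastgreedy(
                weights="weight").as_clustering()
            q_igraph = gi.modularity(clustering, weights="weight")
            assert p.Q == pytest.approx(q_igraph, abs=1e-10)

    def test_deterministic_bit_for_bit(self):
        rng = np.random.default_rng(13)
        A = random_weighted_graph(rng, 30, 90)
        g = WeightedGraph.from_dense(A)
        p1, d1 = fast_greedy(g, r=0.5)
        p2, d2 = fast_greedy(g, r=0.5)
        assert p1.assignment == p2.assignment
        assert p1.Q == p2.Q
        assert d1.merges == d2.merges

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            fast_greedy(WeightedGraph.from_dense(np.zeros((3, 3))), r=0.0)

    def test_isolated_nodes_stay_singletons(self):
        A = np.zeros((5, 5))
        A[0, 1] = A[1, 0] = 1.0
        p, _ = fast_greedy(WeightedGraph.from_dense(A), r=0.0)
        assert p.assignment[2] != p.assignment[3]
        assert p.assignment[0] == p.assignment[1]


class TestResolutionSweep:
    def test_ids_assigned_in_discovery_order(self):
        g = two_disjoint_edges()
        registry = resolution_sweep(g, [0.0])
        assert [c.tc_id for c in registry.communities] == [
            "TC:0000001", "TC:0000002"]
        assert registry.partitions[0.0] == ["TC:0000001", "TC:0000002"]

    def test_duplicate_resolutions_deduplicate_members(self):
        g = two_disjoint_edges()
        registry = resolution_sweep(g, [0.0, 0.0])
        assert len(registry.communities) == 2
        assert registry.communities[0].resolutions == [0.0]
        assert registry.partitions[0.0] == ["TC:0000001", "TC:0000002"]

    def test_identical_partitions_at_two_resolutions_share_ids(self):
        g = two_disjoint_edges()
        registry = resolution_sweep(g, [0.0, 0.001])
        assert len(registry.communities) == 2
        assert registry.communities[0].resolutions == [0.0, 0.001]

    def test_planted_blocks_recovered_at_some_resolution(self, small_bundle):
        import termcommunities as tc

        net = tc.project_term_network(tc.build_bipartite(
            small_bundle["annotations"]))
        g = WeightedGraph.from_term_network(net)
        registry = resolution_sweep(g, [0.0, 1.0, 5.0])
        term_block = small_bundle["term_block"]
        blocks = {}
        for t, b in term_block.items():
            if t in set(net.term_index):
                blocks.setdefault(b, set()).add(t)
        registered = {frozenset(c.members) for c in registry.communities}
        # every planted block's annotated leaf terms land whole inside one
        # registered community, and distinct blocks land in distinct ones
        homes = []
        for b in blocks.values():
            home = [m for m in registered if frozenset(b) <= m]
            assert home, "planted block split across communities at every r"
            homes.append(min(home, key=len))
        assert len(set(homes)) == len(blocks)

    def test_mean_size_non_increasing_in_resolution(self):
        from termcommunities.synthetic import (
            SyntheticConfig, make_annotations, make_ontology)
        import termcommunities as tc

        r_grid = [0.0, 1.0, 5.0, 20.0]
        mean_sizes = np.zeros(len(r_grid))
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SyntheticConfig(n_terms=120, n_genes=150, seed=seed)
            table, _, _ = make_annotations(make_ontology(cfg), cfg)
            g = WeightedGraph.from_term_network(
                tc.project_term_network(tc.build_bipartite(table)))
            registry = resolution_sweep(g, r_grid)
            summary = community_size_summary(registry)
            mean_sizes += [summary[r]["mean_size"] for r in r_grid]
        mean_sizes /= n_seeds
        assert all(a >= b for a, b in zip(mean_sizes, mean_sizes[1:]))

    def test_registry_tsv_roundtrip(self, tmp_path):
        g = two_disjoint_edges()
        g.node_labels = ["GO:1", "GO:2", "GO:3", "GO:4"]
        registry = resolution_sweep(g, [0.0, 2.0])
        registry.write_tsv(tmp_path / "reg.tsv")
        back = CommunityRegistry.read_tsv(tmp_path / "reg.tsv")
        assert {c.tc_id: c.members for c in back.communities} == {
            c.tc_id: c.members for c in registry.communities}
        assert back.partitions.keys() == registry.partitions.keys()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            resolution_sweep(two_disjoint_edges(), [])
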