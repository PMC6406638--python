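"""Graph measures against brute-force and networkx oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from ntenet.graphs import (BinaryDigraph, MOTIF_CLASS_CODES,
                           N_MOTIF_CLASSES, binarize,
                           characteristic_path_length,
                           clustering_coefficients, connectivity_density,
                           motif_census, node_strengths, random_reference,
                           small_world_index, transitivity)

from conftest import NODE_LABELS_14, random_digraph

# ---------------------------------------------------------------------------
# Independent oracles


_EDGES3 = ((0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1))


def oracle_triad_class(adj3):
    """Canonical form by explicit enumeration of all 6 relabelings;
    written independently of the implementation's lookup table."""
    edges = {(a, b) for a in range(3) for b in range(3)
             if a != b and adj3[b][a]}
    und = {frozenset(e) for e in edges}
    if len(und) < 2:
        return None  # weakly disconnected
    best = None
    for perm in itertools.permutations(range(3)):
        code = 0
        for bit, (a, b) in enumerate(_EDGES3):
            if (perm.index(a), perm.index(b)) in edges:
                code |= 1 << bit
        if best is None or code < best:
            best = code
    return best


def oracle_motif_counts(g):
    counts = {}
    a = g.adjacency
    for i, j, k in itertools.combinations(range(g.n_nodes), 3):
        sub = [[a[np.ix_([i, j, k], [i, j, k])][r][c] for c in range(3)]
               for r in range(3)]
        cls = oracle_triad_class(sub)
        if cls is not None:
            counts[cls] = counts.get(cls, 0) + 1
    return counts


def oracle_clustering(g):
    """Per-node triangle count by explicit neighbour loops."""
    a = g.adjacency.astype(int)
    n = g.n_nodes
    out = np.zeros(n)
    for i in range(n):
        tri = 0
        for j in range(n):
            for k in range(n):
                if j == i or k == i or j == k:
                    continue
                tri += (a[j, i] + a[i, j]) * (a[k, i] + a[i, k]) \
                    * (a[k, j] + a[j, k])
        tri /= 2.0  # each unordered triangle counted for both (j,k) orders
        d_tot = a[:, i].sum() + a[i, :].sum()
        d_bi = int((a[:, i] & a[i, :].astype(bool)).sum())
        denom = d_tot * (d_tot - 1) - 2 * d_bi
        out[i] = tri / denom if denom > 0 else 0.0
    return out


def to_nx(g):
    out = nx.DiGraph()
    out.add_nodes_from(range(g.n_nodes))
    for src, tgt in g.edges():
        out.add_edge(src, tgt)
    return out


def complete_digraph():
    a = ~np.eye(14, dtype=bool)
    return BinaryDigraph(a, NODE_LABELS_14)


def empty_digraph():
    return BinaryDigraph(np.zeros((14, 14), bool), NODE_LABELS_14)


# ---------------------------------------------------------------------------


class TestBinarize:
    def test_strictly_above_threshold(self):
        m = np.zeros((14, 14))
        m[2, 1] = 0.001   # exactly at threshold: excluded
        m[3, 1] = 0.0011  # above: included
        g = binarize(m, 0.001)
        assert not g.adjacency[2, 1]
        assert g.adjacency[3, 1]
        assert g.n_edges == 1

    def test_all_half_gives_complete_graph(self):
        m = np.full((14, 14), 0.5) * ~np.eye(14, dtype=bool)
        assert binarize(m, 0.001).n_edges == 182

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((14, 14)), -0.1)


class TestConnectivityDensity:
    def test_complete_graph_is_one(self):
        assert connectivity_density(complete_digraph()) == 1.0

    def test_empty_graph_is_zero(self):
        assert connectivity_density(empty_digraph()) == 0.0

    def test_half_density(self):
        g = random_digraph(seed=1)
        adj = np.zeros((14, 14), bool)
        pairs = [(i, j) for i in range(14) for j in range(14) if i != j]
        for i, j in pairs[:91]:
            adj[i, j] = True
        assert connectivity_density(BinaryDigraph(adj, NODE_LABELS_14)) \
            == 0.5


class TestMotifCensus:
    def test_thirteen_classes_exist(self):
        assert N_MOTIF_CLASSES == 13

    def test_empty_graph_counts_nothing(self):
        assert motif_census(empty_digraph()).total == 0

    def test_complete_graph_all_triples_fully_bidirectional(self):
        census = motif_census(complete_digraph())
        assert census.total == 364  # C(14,3)
        # the all-mutual class is the full 6-edge configuration
        full_class = MOTIF_CLASS_CODES.index(63)
        assert census.counts[full_class] == 364
        assert census.counts.sum() == census.counts[full_class]

    def test_single_directed_cycle(self):
        adj = np.zeros((14, 14), bool)
        adj[1, 0] = adj[2, 1] = adj[0, 2] = True  # 0 -> 1 -> 2 -> 0
        census = motif_census(BinaryDigraph(adj, NODE_LABELS_14))
        assert census.total == 1
        cyc = oracle_triad_class([[0, 0, 1], [1, 0, 0], [0, 1, 0]])
        assert census.counts[MOTIF_CLASS_CODES.index(cyc)] == 1

    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5])
    def test_matches_brute_force_oracle(self, p):
        for rep in range(35):
            g = random_digraph(p=p, seed=rep + int(p * 1000))
            ours = motif_census(g)
            want = oracle_motif_counts(g)
            got = {MOTIF_CLASS_CODES[i]: int(c)
                   for i, c in enumerate(ours.counts) if c}
            assert got == want

    def test_total_bounded_by_triples(self):
        for seed in range(5):
            assert motif_census(random_digraph(seed=seed)).total <= 364


class TestClustering:
    def test_complete_graph_all_ones(self):
        np.testing.assert_allclose(
            clustering_coefficients(complete_digraph()), 1.0)

    def test_empty_graph_all_zeros(self):
        np.testing.assert_array_equal(
            clustering_coefficients(empty_digraph()), 0.0)

    def test_three_cycle(self):
        adj = np.zeros((14, 14), bool)
        adj[1, 0] = adj[2, 1] = adj[0, 2] = True
        c = clustering_coefficients(BinaryDigraph(adj, NODE_LABELS_14))
        expected = oracle_clustering(BinaryDigraph(adj, NODE_LABELS_14))
        np.testing.assert_allclose(c, expected, atol=1e-12)
        assert c[0] == 0.5  # one triangle, d_tot=2, no mutual edges

    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5])
    def test_matches_loop_oracle(self, p):
        for rep in range(10):
            g = random_digraph(p=p, seed=rep + int(p * 100))
            np.testing.assert_allclose(clustering_coefficients(g),
                                       oracle_clustering(g), atol=1e-12)


class TestPathLength:
    def test_complete_graph(self):
        res = characteristic_path_length(complete_digraph())
        assert res.value == 1.0 and res.unreachable_fraction == 0.0

    def test_directed_path(self):
        adj = np.zeros((3, 3), bool)
        adj[1, 0] = adj[2, 1] = True  # a -> b -> c
        res = characteristic_path_length(
            BinaryDigraph(adj, ("a", "b", "c")))
        assert res.value == pytest.approx(4 / 3)
        assert res.unreachable_fraction == pytest.approx(0.5)

    def test_empty_graph_flagged_undefined(self):
        res = characteristic_path_length(empty_digraph())
        assert not res.defined and np.isnan(res.value)

    def test_matches_networkx_bfs(self):
        for seed in range(30):
            g = random_digraph(p=0.2, seed=seed)
            res = characteristic_path_length(g)
            lengths = [d for src, targets in
                       nx.all_pairs_shortest_path_length(to_nx(g))
                       for tgt, d in targets.items() if src != tgt]
            if lengths:
                assert res.value == pytest.approx(np.mean(lengths),
                                                  abs=1e-12)
                n_pairs = g.n_nodes * (g.n_nodes - 1)
                assert res.unreachable_fraction == pytest.approx(
                    1 - len(lengths) / n_pairs, abs=1e-12)


class TestRandomReference:
    def test_complete_graph_cannot_be_rewired(self):
        c, l = random_reference(complete_digraph(), n_random=3, seed=0)
        assert c == 1.0 and l == 1.0

    def test_deterministic_given_seed(self):
        g = random_digraph(seed=3)
        assert random_reference(g, 5, seed=9) == \
            random_reference(g, 5, seed=9)

    def test_degree_sequence_preserved(self):
        from ntenet.graphs import rewire_preserving_degrees

        for seed in range(10):
            g = random_digraph(p=0.3, seed=seed + 40)
            r = rewire_preserving_degrees(g, seed)
            np.testing.assert_array_equal(r.adjacency.sum(axis=0),
                                          g.adjacency.sum(axis=0))
            np.testing.assert_array_equal(r.adjacency.sum(axis=1),
                                          g.adjacency.sum(axis=1))
            assert not np.diagonal(r.adjacency).any()

    def test_er_ensemble_transitivity_near_p(self):
        """Degree-preserving rewires of ER graphs keep transitivity near
        the ER expectation p."""
        p = 0.3
        vals = []
        for seed in range(40):
            g = random_digraph(p=p, seed=seed + 500)
            if g.n_edges < 2:
                continue
            c_rand, _ = random_reference(g, n_random=2, seed=seed)
            vals.append(c_rand)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - p) <= 3 * se + 0.02

    def test_sparse_graph_warns_and_returns_own_values(self):
        adj = np.zeros((14, 14), bool)
        adj[1, 0] = True
        g = BinaryDigraph(adj, NODE_LABELS_14)
        with pytest.warns(UserWarning, match="fewer than 2"):
            c, l = random_reference(g, 5, 0)
        assert c == transitivity(g)


class TestSmallWorld:
    def test_complete_graph_sigma_is_one(self):
        res = small_world_index(complete_digraph(), n_random=3, seed=0)
        assert res.sigma == 1.0
        assert (res.C_d, res.C_rand, res.L_d, res.L_rand) == (1, 1, 1, 1)

    def test_sigma_identity_holds(self):
        g = random_digraph(p=0.3, seed=6)
        res = small_world_index(g, n_random=10, seed=1)
        assert res.sigma == pytest.approx(
            (res.C_d / res.C_rand) / (res.L_d / res.L_rand), abs=1e-12)
        assert res.n_random == 10

    def test_ring_lattice_is_small_world(self):
        """A lightly rewired bidirectional ring shows sigma > 1 in nearly
        every seed."""
        hits = 0
        for seed in range(20):
            ws = nx.watts_strogatz_graph(14, 4, 0.1, seed=seed)
            adj = np.zeros((14, 14), bool)
            for u, v in ws.edges():
                adj[v, u] = adj[u, v] = True
            res = small_world_index(BinaryDigraph(adj, NODE_LABELS_14),
                                    n_random=50, seed=seed)
            hits += res.sigma > 1
        assert hits >= 18

    def test_dense_random_graph_is_its_own_null(self):
        hits = 0
        for seed in range(20):
            g = random_digraph(p=0.7, seed=seed)
            res = small_world_index(g, n_random=50, seed=seed)
            hits += 0.9 <= res.sigma <= 1.1
        assert hits >= 18


class TestNodeStrengths:
    def test_single_entry(self):
        m = np.zeros((14, 14))
        m[2, 1] = 0.5  # channel 1 -> channel 2
        s = node_strengths(m).strengths
        assert s[1] == 0.5 and s[2] == 0.5
        assert s.sum() == 1.0

    def test_total_is_twice_matrix_sum(self):
        rng = np.random.default_rng(7)
        m = rng.random((14, 14)) * ~np.eye(14, dtype=bool)
        s = node_strengths(m).strengths
        assert s.sum() == pytest.approx(2 * m.sum())

    def test_zero_matrix(self):
        assert node_strengths(np.zeros((14, 14))).strengths.sum() == 0.0


class TestRelabelingInvariance:
    def test_global_measures_unchanged_by_node_permutation(self):
        g = random_digraph(p=0.3, seed=8)
        perm = np.random.default_rng(9).permutation(14)
        gp = BinaryDigraph(g.adjacency[np.ix_(perm, perm)], NODE_LABELS_14)
        assert connectivity_density(g) == connectivity_density(gp)
        np.testing.assert_array_equal(motif_census(g).counts,
                                      motif_census(gp).counts)
        assert transitivity(g) == pytest.approx(transitivity(gp), abs=1e-12)
        assert characteristic_path_length(g).value == pytest.approx(
            characteristic_path_length(gp).value, abs=1e-12)
        assert sorted(clustering_coefficients(g)) == pytest.approx(
            sorted(clustering_coefficients(gp)), abs=1e-12)
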