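import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_census
from mcnet import graphlets
from mcnet.covnet import CovarianceNetwork
from mcnet.graphlets import (
    GraphletCensus,
    build_catalog,
    census_exact,
    census_sampled,
    classify_edges,
    graph_from_edges,
    normalize_census,
    read_edgelist,
    threshold_graph,
    write_edgelist,
)


def _er_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    mask = np.triu(rng.random((n, n)) < p, 1)
    return [(int(i), int(j)) for i, j in zip(*np.nonzero(mask))]


class TestCatalog:
    def test_thirty_classes(self):
        assert build_catalog().n_classes == 30

    def test_per_size_counts(self):
        assert build_catalog().classes_by_size() == {2: 1, 3: 2, 4: 6, 5: 21}

    def test_all_connected(self):
        import networkx as nx

        for edges in build_catalog().edges:
            g = nx.Graph(list(edges))
            assert nx.is_connected(g)

    def test_pairwise_non_isomorphic(self):
        import networkx as nx

        catalog = build_catalog()
        graphs = [nx.Graph(list(e)) for e in catalog.edges]
        for i in range(30):
            for j in range(i + 1, 30):
                if catalog.sizes[i] != catalog.sizes[j]:
                    continue
                assert not nx.is_isomorphic(graphs[i], graphs[j]), (i, j)

    def test_known_low_order_identities(self):
        # pinned class anatomy: sizes and edge counts in the conventional order
        catalog = build_catalog()
        assert catalog.sizes == (2,) + (3,) * 2 + (4,) * 6 + (5,) * 21
        edge_counts = [len(e) for e in catalog.edges]
        assert edge_counts[:9] == [1, 2, 3, 3, 3, 4, 4, 5, 6]
        # trees first within size 5, complete graph last
        assert edge_counts[9:12] == [4, 4, 4]
        assert edge_counts[29] == 10

    def test_equal_degree_sequence_pair_distinguished(self):
        # both have degree sequence (1,2,2,2,3) but different structure
        tadpole = [(0, 1), (1, 2), (0, 2), (2, 3), (3, 4)]  # triangle + 2-path
        banner = [(0, 1), (1, 2), (2, 3), (3, 0), (0, 4)]  # 4-cycle + pendant
        c_tadpole = classify_edges(tadpole)
        c_banner = classify_edges(banner)
        assert c_tadpole == 13
        assert c_banner == 16
        assert c_tadpole != c_banner

    def test_named_anchors(self):
        assert classify_edges([(0, 1)]) == 0
        assert classify_edges([(0, 1), (1, 2)]) == 1
        assert classify_edges([(0, 1), (1, 2), (0, 2)]) == 2
        assert classify_edges([(0, 1), (1, 2), (2, 3), (3, 4)]) == 9  # 5-path
        assert classify_edges([(0, 1), (0, 2), (0, 3), (0, 4)]) == 11  # 5-star
        assert classify_edges([(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)]) == 15  # C5
        import itertools

        assert classify_edges(list(itertools.combinations(range(5), 2))) == 29  # K5


class TestThresholdGraph:
    def _net(self, rho):
        rho = np.asarray(rho, dtype=float)
        np.fill_diagonal(rho, 1.0)
        return CovarianceNetwork(rho=rho, n_subjects=10)

    def test_complete_at_low_positive_threshold(self):
        rho = np.full((4, 4), 0.5)
        g = threshold_graph(self._net(rho), 0.4)
        assert g.n_edges == 6
        assert g.rule == "rho >= t"

    def test_empty_at_negative_threshold(self):
        rho = np.full((4, 4), 0.5)
        g = threshold_graph(self._net(rho), -0.2)
        assert g.n_edges == 0
        assert g.n_nodes == 4

    def test_five_node_hand_rule(self):
        rho = np.zeros((5, 5))
        pairs = {
            (0, 1): -0.5, (0, 2): 0.3, (0, 3): -0.2, (0, 4): 0.05,
            (1, 2): 0.25, (1, 3): -0.45, (1, 4): 0.6,
            (2, 3): -0.1, (2, 4): 0.2, (3, 4): -0.3,
        }
        for (i, j), v in pairs.items():
            rho[i, j] = rho[j, i] = v
        net = self._net(rho)
        neg = threshold_graph(net, -0.2)
        assert {tuple(e) for e in neg.edges.tolist()} == {
            (0, 1), (0, 3), (1, 3), (3, 4)
        }
        pos = threshold_graph(net, 0.2)
        assert {tuple(e) for e in pos.edges.tolist()} == {
            (0, 2), (1, 2), (1, 4), (2, 4)
        }

    def test_zero_threshold_rejected(self):
        with pytest.raises(ValueError, match="t = 0"):
            threshold_graph(self._net(np.zeros((3, 3))), 0.0)


class TestCensusExact:
    def test_triangle(self):
        counts = census_exact(graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])).counts
        expected = np.zeros(30, dtype=int)
        expected[0], expected[2] = 3, 1
        assert np.array_equal(counts, expected)

    def test_path_p4(self):
        counts = census_exact(graph_from_edges(4, [(0, 1), (1, 2), (2, 3)])).counts
        expected = np.zeros(30, dtype=int)
        expected[0], expected[1], expected[3] = 3, 2, 1
        assert np.array_equal(counts, expected)

    def test_star_k14(self):
        counts = census_exact(
            graph_from_edges(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
        ).counts
        expected = np.zeros(30, dtype=int)
        expected[0], expected[1], expected[4], expected[11] = 4, 6, 4, 1
        assert np.array_equal(counts, expected)

    def test_matches_brute_force_oracle_er12(self):
        for seed in range(5):
            edges = _er_graph(12, 0.3, seed)
            counts = census_exact(graph_from_edges(12, edges)).counts
            assert np.array_equal(counts, brute_force_census(12, edges)), seed

    def test_isomorphism_invariance_under_relabeling(self, rng):
        n = 15
        edges = _er_graph(n, 0.25, 3)
        counts_a = census_exact(graph_from_edges(n, edges)).counts
        perm = rng.permutation(n)
        relabeled = [(int(perm[a]), int(perm[b])) for a, b in edges]
        counts_b = census_exact(graph_from_edges(n, relabeled)).counts
        assert np.array_equal(counts_a, counts_b)

    def test_guardrail(self):
        edges = _er_graph(30, 0.5, 0)
        with pytest.raises(ValueError, match="census_sampled"):
            census_exact(graph_from_edges(30, edges), max_subgraphs=100)


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 10_000), st.integers(4, 9))
def test_property_exact_census_equals_subset_oracle(seed, n):
    edges = _er_graph(n, 0.35, seed)
    counts = census_exact(graph_from_edges(n, edges)).counts
    assert np.array_equal(counts, brute_force_census(n, edges))


class TestCensusSampled:
    def test_triangle_converges(self):
        g = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        census = census_sampled(g, n_samples=500, seed=0)
        assert census.counts[0] == 3
        assert census.counts[2] == pytest.approx(1.0, abs=1e-9)
        assert np.all(census.counts[np.r_[1, 3:30]] == 0)

    def test_fifty_node_within_three_se(self):
        checks, hits = 0, 0
        for seed in range(6):
            edges = _er_graph(50, 0.12, seed + 20)
            g = graph_from_edges(50, edges)
            exact = census_exact(g).counts
            sampled = census_sampled(g, n_samples=6000, seed=seed)
            for i in range(30):
                if exact[i] > 0 and sampled.standard_errors[i] > 0:
                    checks += 1
                    err = abs(sampled.counts[i] - exact[i])
                    hits += err <= 3 * sampled.standard_errors[i]
        assert checks > 50
        assert hits / checks >= 0.95

    def test_se_scaling_sqrt2(self):
        edges = _er_graph(40, 0.15, 7)
        g = graph_from_edges(40, edges)
        se_small = []
        se_big = []
        for seed in range(4):
            se_small.append(census_sampled(g, n_samples=2000, seed=seed).standard_errors)
            se_big.append(census_sampled(g, n_samples=4000, seed=seed + 50).standard_errors)
        se_small = np.mean(se_small, axis=0)
        se_big = np.mean(se_big, axis=0)
        mask = (se_small > 0) & (se_big > 0)
        ratio = np.mean(se_small[mask] / se_big[mask])
        assert 1.2 < ratio < 1.65  # ~ sqrt(2)

    def test_edgeless_graph_warns_zero(self):
        g = graph_from_edges(5, [])
        with pytest.warns(UserWarning, match="edgeless"):
            census = census_sampled(g, n_samples=10, seed=0)
        assert np.all(census.counts == 0)

    def test_reproducible(self):
        g = graph_from_edges(20, _er_graph(20, 0.2, 1))
        a = census_sampled(g, n_samples=500, seed=9)
        b = census_sampled(g, n_samples=500, seed=9)
        assert np.array_equal(a.counts, b.counts)


class TestNormalizeCensus:
    def test_all_zero_counts(self):
        fstar = normalize_census(GraphletCensus(np.zeros(30), "exact")).fstar
        assert np.allclose(fstar, np.log10(1 + 1 / 30))
        assert fstar[0] == pytest.approx(0.014240, abs=5e-7)

    def test_triangle_census_hand_values(self):
        counts = np.zeros(30)
        counts[0], counts[2] = 3, 1
        fstar = normalize_census(GraphletCensus(counts, "exact")).fstar
        # sum(f+1) = 34
        assert fstar[0] == pytest.approx(np.log10(1 + 4 / 34), abs=1e-12)
        assert fstar[2] == pytest.approx(np.log10(1 + 2 / 34), abs=1e-12)
        assert fstar[5] == pytest.approx(np.log10(1 + 1 / 34), abs=1e-12)
        assert fstar[0] == pytest.approx(0.048305, abs=5e-7)
        assert fstar[2] == pytest.approx(0.024824, abs=5e-7)

    def test_strictly_positive_and_monotone(self, rng):
        counts = rng.integers(0, 1000, 30).astype(float)
        fstar = normalize_census(GraphletCensus(counts, "exact")).fstar
        assert np.all(fstar > 0)
        order_counts = np.argsort(counts, kind="stable")
        assert np.all(np.diff(fstar[order_counts]) >= 0)

    def test_increasing_one_count_increases_fstar(self):
        counts = np.arange(30, dtype=float)
        bumped = counts.copy()
        bumped[12] += 5
        a = normalize_census(GraphletCensus(counts, "exact")).fstar
        # compare at the same denominator convention: recompute share directly
        share_a = (counts[12] + 1) / (counts + 1).sum()
        share_b = (bumped[12] + 1) / (counts + 1).sum()
        assert share_b > share_a
        assert normalize_census(GraphletCensus(bumped, "exact")).fstar[12] > a[12]

    def test_negative_counts_rejected(self):
        counts = np.zeros(30)
        counts[3] = -1
        with pytest.raises(ValueError, match="negative"):
            normalize_census(GraphletCensus(counts, "exact"))

    def test_prose_variant_negative_everywhere(self):
        counts = np.arange(30, dtype=float)
        fstar = normalize_census(GraphletCensus(counts, "exact"), variant="prose").fstar
        assert np.all(fstar < 0)


class TestGraphIO:
    def test_edgelist_roundtrip(self, tmp_path):
        g = graph_from_edges(10, _er_graph(10, 0.3, 2))
        path = tmp_path / "g.tsv"
        write_edgelist(g, path)
        g2 = read_edgelist(path)
        assert g2.n_nodes == g.n_nodes
        assert np.array_equal(g2.edges, g.edges)

    def test_graphml_readable_by_networkx(self, tmp_path):
        import networkx as nx

        g = graph_from_edges(6, [(0, 1), (2, 3)])
        path = tmp_path / "g.graphml"
        graphlets.write_graphml(g, path)
        loaded = nx.read_graphml(path)
        assert loaded.number_of_nodes() == 6
        assert loaded.number_of_edges() == 2
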