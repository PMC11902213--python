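import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rhizoq.errors import AlignmentError, DomainError
from rhizoq.io import CountTable, Network, TaxonomyMap
from rhizoq.network import (
    abundance_filter,
    build_network,
    correlation_matrix,
    hub_report,
    topology,
)

from .oracles import spearman_oracle, topology_oracle


def _as_network(g: nx.Graph, rs=None) -> Network:
    for i, (u, v) in enumerate(g.edges):
        r = rs[i] if rs is not None else 0.9
        g.edges[u, v].update(r=r, p=0.001, sign="+" if r >= 0 else "-")
    return Network(g)


class TestAbundanceFilter:
    def test_hand_computed_mean_threshold(self):
        counts = CountTable(
            pd.DataFrame([[98, 1, 1], [96, 2, 2]], index=["s1", "s2"],
                         columns=["a", "b", "c"])
        )
        out = abundance_filter(counts, 0.01)
        # means: a 97%, b 1.5%, c 1.5% -> all exceed 1%
        assert out.taxon_ids == ["a", "b", "c"]
        out2 = abundance_filter(counts, 0.02)
        assert out2.taxon_ids == ["a"]

    def test_zero_threshold_is_identity(self, toy_counts):
        out = abundance_filter(toy_counts, 0.0)
        pd.testing.assert_frame_equal(out.data, toy_counts.data)

    def test_extreme_threshold_warns_when_everything_drops(self):
        counts = CountTable(
            pd.DataFrame([[98, 1, 1], [96, 2, 2]], index=["s1", "s2"],
                         columns=["a", "b", "c"])
        )
        with pytest.warns(UserWarning, match="every taxon"):
            out = abundance_filter(counts, 0.99)
        assert out.taxon_ids == []

    def test_threshold_domain(self, toy_counts):
        with pytest.raises(DomainError):
            abundance_filter(toy_counts, 1.0)


class TestCorrelationMatrix:
    def _table(self, arr, taxa):
        return CountTable(
            pd.DataFrame(arr, columns=taxa,
                         index=[f"s{i}" for i in range(len(arr))])
        )

    def test_monotone_transform_gives_unit_spearman(self):
        a = np.array([1, 3, 2, 5, 4, 6])
        table = self._table(np.column_stack([a, 2 * a]), ["A", "B"])
        r, p = correlation_matrix(table, use_relative=False)
        assert r.loc["A", "B"] == pytest.approx(1.0)

    def test_antitone_gives_minus_one(self):
        a = np.array([1, 3, 2, 5, 4, 6])
        b = 10 - a
        table = self._table(np.column_stack([a, b, a + b + 1]), ["A", "B", "C"])
        r, _ = correlation_matrix(table, use_relative=False)
        assert r.loc["A", "B"] == pytest.approx(-1.0)

    def test_matches_rank_correlation_oracle(self):
        rng = np.random.default_rng(5)
        arr = rng.integers(0, 50, size=(20, 4)) + 1
        table = self._table(arr, list("ABCD"))
        r, _ = correlation_matrix(table, use_relative=False)
        for i, a in enumerate("ABCD"):
            for b in "ABCD"[i + 1:]:
                expected = spearman_oracle(
                    arr[:, ord(a) - 65], arr[:, ord(b) - 65]
                )
                assert r.loc[a, b] == pytest.approx(expected, abs=1e-12)

    def test_constant_taxon_recorded_missing_with_warning(self):
        arr = np.column_stack(
            [[1, 2, 3, 4, 5], [5, 5, 5, 5, 5], [2, 4, 6, 8, 10]]
        )
        table = self._table(arr, list("ABC"))
        with pytest.warns(UserWarning, match="constant"):
            r, p = correlation_matrix(table, use_relative=False)
        assert np.isnan(r.loc["A", "B"])
        assert r.loc["A", "C"] == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        table = self._table([[1, 2], [3, 4], [5, 6]], ["A", "B"])
        with pytest.raises(DomainError, match="4 samples"):
            correlation_matrix(table)


class TestBuildNetwork:
    def _matrices(self, r_ab, p_ab):
        taxa = ["A", "B"]
        r = pd.DataFrame([[1.0, r_ab], [r_ab, 1.0]], index=taxa, columns=taxa)
        p = pd.DataFrame([[0.0, p_ab], [p_ab, 0.0]], index=taxa, columns=taxa)
        return r, p

    def test_strict_threshold_boundaries(self):
        net = build_network(*self._matrices(0.61, 0.005))
        assert net.n_edges == 1
        net = build_network(*self._matrices(0.60, 0.005))
        assert net.n_edges == 0
        net = build_network(*self._matrices(0.61, 0.01))
        assert net.n_edges == 0

    def test_all_insignificant_gives_empty_network(self):
        net = build_network(*self._matrices(0.99, 1.0))
        assert net.n_edges == 0
        assert net.n_nodes == 0  # isolates dropped by default

    def test_keep_isolates_flag(self):
        net = build_network(*self._matrices(0.99, 1.0), keep_isolates=True)
        assert net.n_nodes == 2

    def test_misaligned_matrices_rejected(self):
        r, p = self._matrices(0.9, 0.001)
        p2 = p.rename(columns={"B": "Z"}, index={"B": "Z"})
        with pytest.raises(AlignmentError):
            build_network(r, p2)

    def test_node_annotation_from_taxonomy(self):
        tax = TaxonomyMap({"A": ("gA", "Pseudomonadota")})
        abund = pd.Series({"A": 0.3, "B": 0.1})
        net = build_network(
            *self._matrices(-0.9, 0.001), taxonomy=tax, mean_abundance=abund
        )
        assert net.graph.nodes["A"]["phylum"] == "Pseudomonadota"
        assert net.graph.nodes["B"]["phylum"] == "Unknown"
        assert net.graph.edges["A", "B"]["sign"] == "-"

    def test_edge_set_invariant_under_taxon_relabeling(self):
        rng = np.random.default_rng(2)
        n = 8
        m = rng.uniform(-1, 1, size=(n, n))
        r = pd.DataFrame((m + m.T) / 2)
        np.fill_diagonal(r.values, 1.0)
        pm = rng.uniform(0, 0.05, size=(n, n))
        p = pd.DataFrame((pm + pm.T) / 2)
        np.fill_diagonal(p.values, 0.0)
        taxa = [f"t{i}" for i in range(n)]
        r.index = r.columns = p.index = p.columns = taxa
        net = build_network(r, p)
        perm = list(rng.permutation(taxa))
        net2 = build_network(
            r.loc[perm, perm], p.loc[perm, perm]
        )
        assert {frozenset(e) for e in net.graph.edges} == {
            frozenset(e) for e in net2.graph.edges
        }

    def test_tightening_thresholds_never_adds_edges(self):
        rng = np.random.default_rng(3)
        n = 10
        m = rng.uniform(-1, 1, size=(n, n))
        r = pd.DataFrame((m + m.T) / 2)
        np.fill_diagonal(r.values, 1.0)
        pm = rng.uniform(0, 0.05, size=(n, n))
        p = pd.DataFrame((pm + pm.T) / 2)
        np.fill_diagonal(p.values, 0.0)
        base = {frozenset(e) for e in build_network(r, p).graph.edges}
        stricter_r = {
            frozenset(e) for e in build_network(r, p, r_min=0.8).graph.edges
        }
        stricter_p = {
            frozenset(e)
            for e in build_network(r, p, p_max=0.001).graph.edges
        }
        assert stricter_r <= base
        assert stricter_p <= base


class TestTopology:
    def test_triangle_analytic_values(self):
        net = _as_network(nx.complete_graph(3))
        t = topology(net)
        assert t.nodes == 3
        assert t.edges == 3
        assert t.average_degree == pytest.approx(2.0)
        assert t.clustering_coefficient == pytest.approx(1.0)
        assert t.degree_centralization == pytest.approx(0.0)
        assert t.betweenness_centralization == pytest.approx(0.0)

    def test_star_is_maximally_centralized(self):
        net = _as_network(nx.star_graph(5))
        t = topology(net)
        assert t.degree_centralization == pytest.approx(1.0)
        assert t.betweenness_centralization == pytest.approx(1.0)

    def test_negative_edge_percentage(self):
        g = nx.path_graph(4)
        net = _as_network(g, rs=[0.9, -0.8, -0.7])
        t = topology(net)
        assert t.negative_edge_pct == pytest.approx(100 * 2 / 3)

    @pytest.mark.parametrize("n,p_edge,seed", [
        (8, 0.4, 0), (15, 0.25, 1), (30, 0.15, 2), (30, 0.05, 3), (12, 0.6, 4),
    ])
    def test_matches_brute_force_oracle_on_random_graphs(self, n, p_edge, seed):
        """Topology metrics agree with explicit triangle counting and
        all-pairs shortest-path betweenness on Erdős–Rényi graphs."""
        g = nx.gnp_random_graph(n, p_edge, seed=seed)
        rng = np.random.default_rng(seed)
        rs = rng.uniform(-1, 1, size=g.number_of_edges())
        net = _as_network(g, rs=rs)
        t = topology(net)
        adj = {v: set(g.neighbors(v)) for v in g.nodes}
        signs = {e: np.sign(r) for e, r in zip(g.edges, rs)}
        expected = topology_oracle(adj, signs)
        assert t.clustering_coefficient == pytest.approx(
            expected["clustering_coefficient"], abs=1e-9
        )
        assert t.degree_centralization == pytest.approx(
            expected["degree_centralization"], abs=1e-9
        )
        assert t.betweenness_centralization == pytest.approx(
            expected["betweenness_centralization"], abs=1e-9
        )
        assert t.average_degree == pytest.approx(expected["average_degree"])
        assert t.negative_edge_pct == pytest.approx(
            expected["negative_edge_pct"]
        )

    def test_small_network_centralization_missing_with_warning(self):
        net = _as_network(nx.path_graph(2))
        with pytest.warns(UserWarning, match="centralization"):
            t = topology(net)
        assert t.degree_centralization is None
        assert t.betweenness_centralization is None


class TestHubReport:
    def test_star_center_ranks_first(self):
        net = _as_network(nx.star_graph(5))
        report = hub_report(net)
        assert report.iloc[0]["degree"] == 5

    def test_signed_neighbor_counts(self):
        g = nx.Graph()
        for v, r in [("b", -0.9), ("c", -0.8), ("d", -0.7), ("e", 0.9)]:
            g.add_edge("a", v, r=r, p=0.001, sign="+" if r >= 0 else "-")
        report = hub_report(Network(g))
        row = report[report["taxon"] == "a"].iloc[0]
        assert row["positive_neighbors"] == 1
        assert row["negative_neighbors"] == 3

    def test_matches_hand_enumeration_with_tie_break(self):
        g = nx.Graph()
        edges = [("x", "y", 0.9), ("x", "z", 0.8), ("y", "z", -0.7),
                 ("w", "x", 0.65)]
        for u, v, r in edges:
            g.add_edge(u, v, r=r, p=0.005, sign="+" if r >= 0 else "-")
        report = hub_report(Network(g), top_k=4)
        assert list(report["taxon"]) == ["x", "y", "z", "w"]
        assert list(report["degree"]) == [3, 2, 2, 1]
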