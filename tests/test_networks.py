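import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualtrace import networks
from dualtrace.model import RegionCountTable

from conftest import make_table
from oracles import brute_force_metrics, best_two_partition, correlation_p_oracle


def net_from_edges(edges, nodes=None):
    G = nx.Graph()
    if nodes:
        G.add_nodes_from(nodes)
    for a, b in edges:
        G.add_edge(a, b, r=1.0, p=0.0)
    return networks.FunctionalNetwork(graph=G, r_min=0.0, alpha=1.0)


class TestPairwiseCorrelations:
    def test_identical_vectors_correlate_perfectly(self):
        table = make_table({"A": [1, 2, 3, 4, 5], "B": [1, 2, 3, 4, 5]})
        corr = networks.pairwise_correlations(table)
        assert corr.r[0, 1] == pytest.approx(1.0)

    def test_negated_vector_anticorrelates(self):
        table = make_table({"A": [1, 2, 3, 4, 5], "B": [-1, -2, -3, -4, -5]})
        corr = networks.pairwise_correlations(table)
        assert corr.r[0, 1] == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self, five_mouse_table):
        corr = networks.pairwise_correlations(five_mouse_table)
        pivot = networks.density_pivot(five_mouse_table)
        for i, a in enumerate(corr.regions):
            for j, b in enumerate(corr.regions):
                x, y = pivot[a].to_numpy(), pivot[b].to_numpy()
                # direct evaluation of r = cov / (sd_x sd_y)
                cov = np.mean((x - x.mean()) * (y - y.mean()))
                oracle = cov / (x.std() * y.std())
                assert corr.r[i, j] == pytest.approx(oracle, abs=1e-12)

    def test_constant_region_reported_missing_with_warning(self):
        table = make_table({"A": [1, 2, 3, 4], "B": [5, 5, 5, 5]})
        with pytest.warns(UserWarning, match="missing"):
            corr = networks.pairwise_correlations(table)
        assert np.isnan(corr.r[0, 1])

    def test_symmetry_and_unit_diagonal(self, five_mouse_table):
        corr = networks.pairwise_correlations(five_mouse_table)
        np.testing.assert_allclose(corr.r, corr.r.T)
        np.testing.assert_allclose(np.diag(corr.r), 1.0)
        np.testing.assert_allclose(corr.p, corr.p.T)


class TestCorrelationPvalue:
    def test_zero_correlation_gives_p_one(self):
        assert networks.correlation_pvalue(0.0, 10) == pytest.approx(1.0)

    def test_perfect_correlation_gives_p_zero(self):
        assert networks.correlation_pvalue(1.0, 5) == 0.0
        assert networks.correlation_pvalue(-1.0, 5) == 0.0

    def test_known_value_r09_n5(self):
        # t = 0.9 sqrt(3) / sqrt(0.19) ≈ 3.576 on 3 df → p ≈ 0.0374
        p = networks.correlation_pvalue(0.9, 5)
        assert p == pytest.approx(0.0374, abs=5e-4)
        assert p == pytest.approx(correlation_p_oracle(0.9, 5), abs=1e-10)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            networks.correlation_pvalue(0.5, 2)

    @given(
        r=st.floats(0.05, 0.95),
        n1=st.integers(4, 30),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_p_decreases_with_strength_and_sample_size(self, r, n1):
        p_weak = networks.correlation_pvalue(r * 0.5, n1)
        p_strong = networks.correlation_pvalue(r, n1)
        assert p_strong < p_weak
        assert networks.correlation_pvalue(r, n1 + 5) < networks.correlation_pvalue(r, n1)


class TestBuildNetwork:
    def corr(self, r, p):
        return networks.CorrelationMatrix(
            regions=["A", "B"],
            r=np.array([[1.0, r], [r, 1.0]]),
            p=np.array([[0.0, p], [p, 0.0]]),
            n=np.full((2, 2), 8),
        )

    def test_strong_significant_pair_becomes_edge(self):
        net = networks.build_network(self.corr(0.95, 0.001), alpha=0.01)
        assert net.graph.has_edge("A", "B")

    def test_insignificant_pair_dropped(self):
        net = networks.build_network(self.corr(0.95, 0.02), alpha=0.01)
        assert not net.graph.has_edge("A", "B")

    def test_anticorrelated_pair_kept_with_negative_weight(self):
        net = networks.build_network(self.corr(-0.95, 0.001), alpha=0.01)
        assert net.graph.edges["A", "B"]["r"] == pytest.approx(-0.95)

    def test_signed_mode_drops_anticorrelations(self):
        net = networks.build_network(
            self.corr(-0.95, 0.001), alpha=0.01, use_absolute=False
        )
        assert not net.graph.has_edge("A", "B")

    @given(
        alpha1=st.floats(0.001, 0.5),
        alpha2=st.floats(0.001, 0.5),
        rmin1=st.floats(0.0, 0.99),
        rmin2=st.floats(0.0, 0.99),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_edge_set_monotone_in_both_thresholds(self, alpha1, alpha2, rmin1, rmin2):
        rng = np.random.default_rng(5)
        k = 6
        r = np.clip((rng.random((k, k)) * 2 - 1), -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        p = rng.random((k, k))
        p = (p + p.T) / 2
        np.fill_diagonal(p, 0.0)
        corr = networks.CorrelationMatrix(
            regions=list("ABCDEF"), r=r, p=p, n=np.full((k, k), 8)
        )
        lo_a, hi_a = sorted((alpha1, alpha2))
        lo_r, hi_r = sorted((rmin1, rmin2))
        tight = networks.build_network(corr, r_min=hi_r, alpha=lo_a)
        loose = networks.build_network(corr, r_min=lo_r, alpha=hi_a)
        assert set(tight.graph.edges) <= set(loose.graph.edges)


class TestNodeMetrics:
    def test_triangle(self):
        m = networks.node_metrics(net_from_edges([("A", "B"), ("B", "C"), ("A", "C")]))
        assert (m.per_node["degree"] == 2).all()
        assert (m.per_node["clustering"] == 1.0).all()
        assert (m.per_node["efficiency"] == 1.0).all()
        assert (m.per_node["betweenness"] == 0.0).all()

    def test_path_of_three(self):
        m = networks.node_metrics(net_from_edges([("A", "B"), ("B", "C")]))
        row_b = m.per_node.set_index("node").loc["B"]
        assert row_b["clustering"] == 0.0
        assert row_b["betweenness"] == 1.0
        assert m.global_efficiency == pytest.approx((1 + 1 + 0.5) / 3)

    def test_star_betweenness(self):
        m = networks.node_metrics(
            net_from_edges([("hub", "a"), ("hub", "b"), ("hub", "c")])
        )
        per = m.per_node.set_index("node")["betweenness"]
        assert per["hub"] == 3.0
        assert (per.drop("hub") == 0.0).all()

    def test_isolated_node_has_zero_clustering_and_efficiency(self):
        m = networks.node_metrics(net_from_edges([("A", "B")], nodes=["A", "B", "C"]))
        row = m.per_node.set_index("node").loc["C"]
        assert row["clustering"] == 0.0 and row["efficiency"] == 0.0

    @pytest.mark.parametrize("idx", [5, 30, 80, 150, 208, 250])
    def test_matches_brute_force_oracle_on_atlas_graphs(self, idx):
        G = nx.graph_atlas_g()[idx]
        if not nx.is_connected(G):
            G = G.subgraph(max(nx.connected_components(G), key=len)).copy()
        G = nx.convert_node_labels_to_integers(G)
        m = networks.node_metrics(net_from_edges(list(G.edges), nodes=list(G.nodes)))
        oracle = brute_force_metrics(G.number_of_nodes(), list(G.edges))
        per = m.per_node.set_index("node")
        for v in G.nodes:
            assert per.loc[v, "degree"] == oracle["degree"][v]
            assert per.loc[v, "clustering"] == pytest.approx(oracle["clustering"][v])
            assert per.loc[v, "efficiency"] == pytest.approx(oracle["efficiency"][v])
            assert per.loc[v, "betweenness"] == pytest.approx(oracle["betweenness"][v])


class TestThresholdSweep:
    def corr_pair(self):
        table = make_table(
            {
                "A": [1, 2, 3, 4, 5, 6],
                "B": [1.1, 2.2, 2.9, 4.1, 5.2, 5.9],
                "C": [6, 4, 5, 2, 3, 1],
            }
        )
        return {"CT": networks.pairwise_correlations(table)}

    def test_alpha_one_extreme_keeps_complete_graph(self):
        corrs = self.corr_pair()
        sweep = networks.threshold_sweep(corrs, [0.999], r_min=0.0)
        assert sweep["mean_degree"].iloc[0] == pytest.approx(2.0)

    def test_tiny_alpha_empties_graph(self):
        corrs = self.corr_pair()
        sweep = networks.threshold_sweep(corrs, [1e-12], r_min=0.0)
        assert (sweep[["mean_degree", "mean_clustering", "global_efficiency",
                       "mean_betweenness"]].iloc[0] == 0).all()

    def test_mean_degree_nondecreasing_in_alpha(self):
        corrs = self.corr_pair()
        alphas = [1e-6, 1e-3, 0.01, 0.05, 0.2, 0.999]
        sweep = networks.threshold_sweep(corrs, alphas, r_min=0.0)
        degrees = sweep.sort_values("alpha")["mean_degree"].to_numpy()
        assert (np.diff(degrees) >= 0).all()

    def test_unsorted_alphas_rejected(self):
        with pytest.raises(ValueError):
            networks.threshold_sweep(self.corr_pair(), [0.05, 0.01])


class TestPermutationDiff:
    def two_group_tables(self, seed=0, n=6, k=4, shift=None):
        rng = np.random.default_rng(seed)
        regions = [f"R{i}" for i in range(k)]
        ta = make_table(
            {r: rng.normal(100, 10, n).tolist() for r in regions}, group="CT"
        )
        tb = make_table(
            {r: rng.normal(100, 10, n).tolist() for r in regions}, group="IS"
        )
        return ta, tb

    def test_identical_data_gives_zero_d_and_p_one(self):
        ta, _ = self.two_group_tables()
        tb = RegionCountTable(ta.df.assign(group="IS"))
        res = networks.permutation_correlation_diff(ta, tb, n_permutations=199, seed=1)
        frame = res.to_frame()
        assert (frame["d"].abs() < 1e-12).all()
        assert (frame["p"] == 1.0).all()

    def test_seeded_determinism(self):
        ta, tb = self.two_group_tables()
        r1 = networks.permutation_correlation_diff(ta, tb, n_permutations=200, seed=42)
        r2 = networks.permutation_correlation_diff(ta, tb, n_permutations=200, seed=42)
        np.testing.assert_array_equal(r1.p, r2.p)
        np.testing.assert_array_equal(r1.d_obs, r2.d_obs)

    def test_pvalues_respect_add_one_bounds(self):
        ta, tb = self.two_group_tables(seed=3)
        res = networks.permutation_correlation_diff(ta, tb, n_permutations=200, seed=0)
        frame = res.to_frame()
        assert (frame["p"] >= 1 / 201).all()
        assert (frame["p"] <= 1.0).all()

    def test_few_permutations_warns(self):
        ta, tb = self.two_group_tables()
        with pytest.warns(UserWarning, match="permutations"):
            networks.permutation_correlation_diff(ta, tb, n_permutations=50, seed=0)

    def test_too_few_mice_rejected(self):
        ta, tb = self.two_group_tables(n=2)
        with pytest.raises(ValueError, match="3 mice"):
            networks.permutation_correlation_diff(ta, tb, n_permutations=200)


class TestKSRegionDistributions:
    def corr_from(self, values, regions=None):
        k = len(values) + 1
        regions = regions or [f"R{i}" for i in range(k)]
        r = np.eye(k)
        r[0, 1:] = r[1:, 0] = values
        return networks.CorrelationMatrix(
            regions=regions, r=r, p=np.zeros((k, k)), n=np.full((k, k), 8)
        )

    def test_identical_distributions(self):
        corr = self.corr_from([0.1, 0.5, 0.9])
        d, p = networks.ks_region_distributions(corr, corr, "R0")
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports_give_d_one(self):
        a = self.corr_from([0.1, 0.2, 0.3])
        b = self.corr_from([0.4, 0.5, 0.6])
        d, _ = networks.ks_region_distributions(a, b, "R0")
        assert d == 1.0

    def test_quarter_shift_gives_d_quarter(self):
        a = self.corr_from([0.1, 0.2, 0.5, 0.6])
        b = self.corr_from([0.1, 0.2, 0.5, 0.9])
        d, _ = networks.ks_region_distributions(a, b, "R0")
        assert d == pytest.approx(0.25)

    def test_too_few_values_rejected(self):
        a = self.corr_from([0.1, 0.2])
        with pytest.raises(ValueError):
            networks.ks_region_distributions(a, a, "R0")


class TestLeadingEigenvectorPartition:
    def test_two_disconnected_triangles_recovered(self):
        edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]
        membership = networks.leading_eigenvector_partition(net_from_edges(edges))
        assert membership[0] == membership[1] == membership[2]
        assert membership[3] == membership[4] == membership[5]
        assert membership[0] != membership[3]
        # brute force over all 2-partitions agrees
        q_best, labels = best_two_partition(6, edges)
        assert networks.modularity(net_from_edges(edges).graph, membership) == (
            pytest.approx(q_best)
        )

    def test_complete_graph_stays_single_community(self):
        edges = [(a, b) for a in range(4) for b in range(a + 1, 4)]
        membership = networks.leading_eigenvector_partition(net_from_edges(edges))
        assert len(set(membership.values())) == 1

    def test_single_edge_plus_isolate(self):
        net = net_from_edges([("A", "B")], nodes=["A", "B", "C"])
        membership = networks.leading_eigenvector_partition(net)
        # leading eigenvalue is zero: no split improves modularity
        assert membership["A"] == membership["B"]

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            networks.leading_eigenvector_partition(net_from_edges([], nodes=["A"]))

    @pytest.mark.parametrize(
        "graph",
        [
            nx.barbell_graph(3, 0),
            nx.barbell_graph(4, 0),
            nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(4)),
            nx.path_graph(8),
            nx.star_graph(4),
        ],
        ids=["barbell33", "barbell44", "K3+K4", "path8", "star5"],
    )
    def test_modular_graphs_attain_brute_force_optimum(self, graph):
        edges = list(graph.edges)
        net = net_from_edges(edges, nodes=list(graph.nodes))
        membership = networks.leading_eigenvector_partition(net)
        q = networks.modularity(net.graph, membership)
        q_best, _ = best_two_partition(graph.number_of_nodes(), edges)
        assert q == pytest.approx(q_best, abs=1e-9)
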