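"""Normalized degree, damping estimation, PageRank, shares, comparisons."""
import numpy as np
import pytest

from mediacite.errors import ConvergenceError
from mediacite.network import CorpusSummary
from mediacite.node_metrics import (
    compare_stages,
    estimate_damping_factor,
    influence_share,
    node_shares,
    normalized_degree,
    pagerank,
)

from conftest import make_network, random_citation_network


class TestNormalizedDegree:
    def test_weighted_strength_over_n_minus_one(self):
        net = make_network([("a", "b", 3), ("c", "a", 2), ("b", "c", 1)])
        ndeg = normalized_degree(net)
        assert ndeg["a"] == pytest.approx(5 / 2)  # strength 3+2, N-1 = 2

    def test_top_activity_value_matches_integer_strength(self):
        # a 414-node network where one outlet accumulates strength 672
        edges = [("hub", f"o{i:03d}", 1) for i in range(413)]
        edges += [(f"o{i:03d}", "hub", 1) for i in range(259)]
        net = make_network(edges)
        assert net.n_nodes == 414
        assert net.strength("hub") == 672
        assert f"{normalized_degree(net)['hub']:.6f}" == "1.627119"

    def test_single_node_raises(self):
        net = make_network([("a", "b", 1)]).induced_subnetwork(["a"])
        with pytest.raises(ValueError):
            normalized_degree(net)


class TestDampingEstimate:
    def test_corpus_scale_ratio(self):
        est = estimate_damping_factor(CorpusSummary(246759, 32556))
        assert round(est.d, 2) == 0.13
        assert est.numerator == 32556 and est.denominator == 246759

    def test_simple_arithmetic(self):
        assert estimate_damping_factor(CorpusSummary(1000, 130)).d == 0.13

    def test_zero_citations(self):
        assert estimate_damping_factor(CorpusSummary(10, 0)).d == 0.0

    def test_ratio_above_one_clamped_with_flag(self):
        est = estimate_damping_factor(CorpusSummary(10, 25))
        assert est.d == 1.0 and est.clamped

    def test_zero_reports_raises(self):
        with pytest.raises(ValueError):
            estimate_damping_factor(CorpusSummary(0, 0))


class TestPageRank:
    def test_d_zero_gives_exact_uniform(self):
        net = random_citation_network(9, 0.3, 1)
        pr = pagerank(net, d=0.0)
        assert all(v == pytest.approx(1 / 9, abs=0) for v in pr.values())

    def test_mutual_pair_symmetric(self):
        net = make_network([("a", "b", 4), ("b", "a", 1)])
        pr = pagerank(net, d=0.7)
        assert pr["a"] == pytest.approx(0.5, abs=1e-9)
        assert pr["b"] == pytest.approx(0.5, abs=1e-9)

    def test_fan_out_matches_linear_system(self):
        from oracles import pagerank_linear_solve

        net = make_network([("a", "b", 2), ("a", "c", 2)])
        pr = pagerank(net, d=0.13)
        exact = pagerank_linear_solve(net, 0.13)
        for v in pr:
            assert pr[v] == pytest.approx(exact[v], abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("d", [0.13, 0.85])
    def test_random_digraphs_match_linear_system(self, seed, d):
        from oracles import pagerank_linear_solve

        net = random_citation_network(5 + seed * 4, 0.15, seed)
        pr = pagerank(net, d=d)
        exact = pagerank_linear_solve(net, d)
        for v in pr:
            assert pr[v] == pytest.approx(exact[v], abs=1e-8)

    @pytest.mark.parametrize("d", [0.0, 0.13, 0.85, 1.0])
    def test_sums_to_one_with_dangling_nodes(self, d):
        net = make_network([("a", "b", 1), ("a", "c", 3), ("d", "a", 2)])
        pr = pagerank(net, d=d)  # b, c are dangling
        assert sum(pr.values()) == pytest.approx(1.0, abs=1e-9)

    def test_weight_sensitivity(self):
        net = make_network([("a", "b", 9), ("a", "c", 1), ("b", "a", 1),
                            ("c", "a", 1)])
        pr = pagerank(net, d=0.85)
        assert pr["b"] > pr["c"]

    def test_spread_grows_with_d(self):
        net = make_network([("a", "b", 1), ("b", "c", 2), ("a", "c", 1)])
        spreads = []
        for d in (0.1, 0.4, 0.7, 0.95):
            pr = pagerank(net, d=d)
            spreads.append(max(pr.values()) - min(pr.values()))
        assert all(x < y for x, y in zip(spreads, spreads[1:]))

    def test_non_convergence_carries_residual(self):
        net = random_citation_network(20, 0.2, 3)
        with pytest.raises(ConvergenceError) as exc:
            pagerank(net, d=0.85, tolerance=1e-15, max_iterations=2)
        assert exc.value.residual > 0


class TestNodeShares:
    def test_influence_share_is_pagerank_percent(self):
        assert influence_share(0.011430) == pytest.approx(1.143)
        assert influence_share(0.004814) == pytest.approx(0.4814)

    def test_shares_sum_to_one_and_hundred(self):
        net = random_citation_network(15, 0.25, 8)
        scores = node_shares(net, pagerank(net, d=0.13))
        assert scores.table["activity_share"].sum() == pytest.approx(1.0, abs=1e-9)
        assert scores.table["influence_share"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_uniform_weights_give_equal_activity(self):
        net = make_network([("a", "b", 2), ("b", "c", 2), ("c", "a", 2)])
        scores = node_shares(net, pagerank(net, d=0.13))
        assert scores.table["activity_share"].nunique() == 1


class TestCompareStages:
    def test_core_size_ratios(self):
        # cores at the published alert-stage scale: 43 vs 192 nodes,
        # 304 vs 2699 edges
        rng = np.random.default_rng(0)

        def dense_net(n, e, tag):
            # ring first so every node enters; random fill to e edges
            edges = {
                (f"{tag}{i:03d}", f"{tag}{(i + 1) % n:03d}") for i in range(n)
            }
            while len(edges) < e:
                u, v = rng.integers(n, size=2)
                if u != v:
                    edges.add((f"{tag}{u:03d}", f"{tag}{v:03d}"))
            return make_network([(u, v, 1) for u, v in edges])

        net1 = dense_net(43, 304, "a")
        net2 = dense_net(192, 2699, "b")
        s1 = node_shares(net1, pagerank(net1, d=0.13))
        s2 = node_shares(net2, pagerank(net2, d=0.13))
        cmpres = compare_stages(
            s1, s2, net1, net2,
            cores=(set(net1.nodes()), set(net2.nodes())),
        )
        assert round(cmpres.core_node_ratio, 2) == 4.47
        assert round(cmpres.core_edge_ratio, 2) == 8.88

    def test_identical_stages_zero_change_unit_ratio(self):
        net = random_citation_network(12, 0.3, 5)
        scores = node_shares(net, pagerank(net, d=0.13))
        cmpres = compare_stages(scores, scores, net, net)
        assert cmpres.node_ratio == 1.0 and cmpres.edge_ratio == 1.0
        assert np.allclose(cmpres.outlets["activity_change"], 0.0)
        assert np.allclose(cmpres.countries["influence_change"], 0.0)

    def test_absent_outlets_reported_as_missing(self):
        net1 = make_network([("a", "b", 1)])
        net2 = make_network([("a", "b", 1), ("b", "c", 1)])
        s1 = node_shares(net1, pagerank(net1, d=0.13))
        s2 = node_shares(net2, pagerank(net2, d=0.13))
        cmpres = compare_stages(s1, s2, net1, net2)
        assert np.isnan(cmpres.outlets.loc["c", "activity_share_s1"])
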