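"""k-shell decomposition, crust profile, crossover core selection."""
import networkx as nx
import pytest

from mediacite.core_periphery import (
    CrustProfile,
    assign_core,
    core_country_matrix,
    core_coverage,
    crust_component_profile,
    k_shell_decomposition,
    select_core_threshold,
)
from mediacite.network import UndirectedGraph

from conftest import make_network, random_undirected


class TestKShell:
    def test_path_is_all_shell_one(self):
        g = UndirectedGraph.from_edges([("a", "b"), ("b", "c")])
        shells = k_shell_decomposition(g)
        assert shells.shell == {"a": 1, "b": 1, "c": 1}
        assert shells.k_max == 1

    def test_triangle_with_pendant(self, triangle_pendant):
        shells = k_shell_decomposition(triangle_pendant)
        assert shells.shell == {"a": 2, "b": 2, "c": 2, "p": 1}

    def test_complete_graph_k4(self):
        g = UndirectedGraph.from_edges(
            [(u, v) for u in "abcd" for v in "abcd" if u < v]
        )
        shells = k_shell_decomposition(g)
        assert set(shells.shell.values()) == {3}

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_min_degree_deletion_oracle(self, seed):
        from oracles import min_degree_deletion_shells

        g = random_undirected(5 + (seed * 7) % 46, 0.15, seed)
        shells = k_shell_decomposition(g)
        assert shells.shell == min_degree_deletion_shells(g)
        # networkx core_number as a second, independent route
        nxg = nx.Graph(g.edges())
        nxg.add_nodes_from(g.nodes())
        core = nx.core_number(nxg)
        assert shells.shell == {v: max(1, core[v]) for v in g.nodes()}

    @pytest.mark.parametrize("seed", range(6))
    def test_shell_bounded_by_degree_and_cores_nested(self, seed):
        g = random_undirected(30, 0.2, seed)
        shells = k_shell_decomposition(g)
        for v in g.nodes():
            if g.degree(v) > 0:
                assert shells.shell[v] <= g.degree(v)
        for k in range(1, shells.k_max + 1):
            assert shells.core_nodes(k + 1) <= shells.core_nodes(k)

    def test_weighted_pruning_mode(self):
        # strength-based pruning strips the weak-weight pendant first
        g = UndirectedGraph.from_edges(
            [("a", "b"), ("b", "c"), ("a", "c"), ("a", "p")]
        )
        weights = {("a", "b"): 5, ("b", "c"): 5, ("a", "c"): 5, ("a", "p"): 1}
        shells = k_shell_decomposition(g, use_strength=True, weights=weights)
        assert shells.shell["p"] < shells.shell["a"]


class TestCrustProfile:
    def test_top_crust_equals_full_graph_component(self, triangle_pendant):
        shells = k_shell_decomposition(triangle_pendant)
        profile = crust_component_profile(triangle_pendant, shells)
        k, largest, _ = profile.sizes[-1]
        assert k == shells.k_max and largest == 4

    def test_two_triangles_hanging_off_clique_core(self):
        clique = [(u, v) for u in "ABCD" for v in "ABCD" if u < v]
        g = UndirectedGraph.from_edges(
            clique
            + [("t", "u"), ("u", "v"), ("t", "v")]
            + [("x", "y"), ("y", "z"), ("x", "z")]
            + [("t", "A"), ("x", "B")]
        )
        shells = k_shell_decomposition(g)
        profile = crust_component_profile(g, shells)
        by_k = {k: (lg, sc) for k, lg, sc in profile.sizes}
        # at k=2 the two triangles are separate crust components
        assert by_k[2] == (3, 3)
        assert by_k[3] == (10, 0)

    def test_largest_component_non_decreasing(self):
        g = random_undirected(40, 0.15, 3)
        shells = k_shell_decomposition(g)
        profile = crust_component_profile(g, shells)
        largest = [lg for _, lg, _ in profile.sizes]
        assert all(a <= b for a, b in zip(largest, largest[1:]))


class TestSelectCoreThreshold:
    def test_crossover_example(self):
        profile = CrustProfile(
            ((1, 5, 4), (2, 6, 5), (3, 7, 6), (4, 30, 3), (5, 32, 2))
        )
        k_star, degenerate = select_core_threshold(profile)
        assert k_star == 4 and not degenerate

    def test_tie_breaks_toward_smallest_k(self):
        # strictly linear growth, second-largest constant
        profile = CrustProfile(
            ((1, 10, 2), (2, 20, 2), (3, 30, 2), (4, 40, 2))
        )
        k_star, _ = select_core_threshold(profile)
        assert k_star == 2  # k=1 has no predecessor; delta ties at 10 after

    def test_single_layer_profile_degenerate(self):
        k_star, degenerate = select_core_threshold(CrustProfile(((1, 9, 0),)))
        assert k_star == 1 and degenerate

    def test_unconstrained_fallback_when_second_always_grows(self):
        profile = CrustProfile(((1, 2, 1), (2, 9, 3), (3, 12, 5)))
        k_star, _ = select_core_threshold(profile)
        assert k_star == 2

    def test_core_periphery_partition_the_nodes(self):
        g = random_undirected(40, 0.2, 11)
        shells = k_shell_decomposition(g)
        assignment = assign_core(g, shells)
        core, periph = assignment.core_nodes, assignment.periphery_nodes
        assert core | periph == set(g.nodes())
        assert not core & periph


class TestCoreCoverage:
    def test_core_is_everything(self):
        net = make_network([("a", "b", 1), ("b", "c", 1)])
        assert core_coverage(net, {"a", "b", "c"}) == 1.0

    def test_star_center_covers_all(self):
        net = make_network([("h", x, 1) for x in ("a", "b", "c", "d")])
        assert core_coverage(net, {"h"}) == 1.0

    def test_partial_coverage_fraction(self):
        edges = [("c1", "c2", 1)]
        edges += [("c1", f"t{i}", 1) for i in range(3)]
        edges += [(f"t{i+3}", "c2", 1) for i in range(3)]
        edges += [("o1", "o2", 1)]
        net = make_network(edges)  # 10 nodes, core touches 6 others
        assert core_coverage(net, {"c1", "c2"}) == pytest.approx(0.8)

    def test_empty_core_is_zero(self):
        net = make_network([("a", "b", 1)])
        assert core_coverage(net, set()) == 0.0


class TestCoreCountryMatrix:
    def test_single_country_core_all_zero(self):
        net = make_network(
            [("a", "b", 2), ("b", "a", 4)], countries={"a": "US", "b": "US"}
        )
        mat = core_country_matrix(net, {"a", "b"})
        assert mat.to_numpy().sum() == 0

    def test_single_cross_edge(self):
        net = make_network(
            [("a", "b", 3)], countries={"a": "US", "b": "CN"}
        )
        mat = core_country_matrix(net, {"a", "b"})
        assert mat.loc["US", "CN"] == 3
        assert mat.to_numpy().sum() == 3

    def test_conservation_and_descending_order(self):
        net = make_network(
            [("a", "b", 5), ("b", "c", 2), ("c", "d", 1), ("d", "a", 7),
             ("a", "a2", 9)],
            countries={"a": "US", "a2": "US", "b": "CN", "c": "GB", "d": "FR"},
        )
        core = {"a", "a2", "b", "c", "d"}
        mat = core_country_matrix(net, core)
        # domestic a->a2 excluded; cross-country total 5+2+1+7
        assert mat.to_numpy().sum() == 15
        totals = mat.sum(axis=1) + mat.sum(axis=0)
        assert list(totals) == sorted(totals, reverse=True)
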