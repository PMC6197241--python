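"""Metabolite graph construction, flux pruning, and centrality."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coculture import network
from coculture.fba_core import FluxSolution
from coculture.model_core import DEFAULT_BOUND
from conftest import build_model
from oracles import brute_force_betweenness


def _solution(fluxes):
    return FluxSolution(fluxes=fluxes, objective_value=0.0, status="optimal",
                        total_absolute_flux=0.0)


class TestBuildGraph:
    def test_product_of_sets_rule(self):
        model = build_model("g", "R", [
            ("R", {"a_c": -1.0, "b_c": -1.0, "c_c": 1.0, "d_c": 1.0},
             0.0, DEFAULT_BOUND),
        ])
        graph = network.build_graph(model)
        assert set(graph.edges(keys=False)) == {
            ("a_c", "c_c"), ("a_c", "d_c"), ("b_c", "c_c"), ("b_c", "d_c")}

    def test_reversible_doubles_edges(self):
        model = build_model("g", "R", [
            ("R", {"a_c": -1.0, "b_c": -1.0, "c_c": 1.0, "d_c": 1.0},
             -DEFAULT_BOUND, DEFAULT_BOUND),
        ])
        assert network.build_graph(model).number_of_edges() == 8

    def test_currency_pair_and_removed_metabolites(self):
        # glc + atp -> g6p + adp: ATP/ADP are both removed outright and a
        # currency pair, leaving the single glc -> g6p edge.
        model = build_model("g", "HEX", [
            ("HEX", {"glc_D_c": -1.0, "atp_c": -1.0, "g6p_c": 1.0, "adp_c": 1.0},
             0.0, DEFAULT_BOUND),
        ])
        graph = network.build_graph(model)
        assert set(graph.edges(keys=False)) == {("glc_D_c", "g6p_c")}

    def test_excluded_subsystems_and_external_reactions_dropped(self):
        model = build_model("g", "R1", [
            ("R1", {"a_c": -1.0, "b_c": 1.0}, 0.0, DEFAULT_BOUND),
            ("R2", {"a_c": -1.0, "b_c": 1.0}, 0.0, DEFAULT_BOUND,
             "Fatty acid synthesis"),
            ("T1", {"a_e": -1.0, "a_c": 1.0}, 0.0, DEFAULT_BOUND),
        ])
        graph = network.build_graph(model)
        assert [d["reaction"] for *_, d in graph.edges(data=True)] == ["R1"]

    def test_order_independent(self):
        reactions = [
            ("R1", {"a_c": -1.0, "b_c": 1.0}, 0.0, DEFAULT_BOUND),
            ("R2", {"b_c": -1.0, "c_c": 1.0}, -DEFAULT_BOUND, DEFAULT_BOUND),
            ("R3", {"c_c": -1.0, "a_c": 1.0}, 0.0, DEFAULT_BOUND),
        ]
        g1 = network.build_graph(build_model("g", "R1", reactions))
        g2 = network.build_graph(build_model("g", "R1", reactions[::-1]))
        assert set(g1.edges(keys=True)) == set(g2.edges(keys=True))


class TestPruneByFlux:
    def _cycle_graph(self):
        model = build_model("g", "R1", [
            ("R1", {"a_c": -1.0, "b_c": 1.0}, 0.0, DEFAULT_BOUND),
            ("R2", {"b_c": -1.0, "c_c": 1.0}, 0.0, DEFAULT_BOUND),
            ("R3", {"c_c": -1.0, "a_c": 1.0}, 0.0, DEFAULT_BOUND),
            ("R4", {"c_c": -1.0, "d_c": 1.0}, 0.0, DEFAULT_BOUND),  # dangling
        ])
        return network.build_graph(model)

    def test_scc_drops_dangling_node(self):
        graph = self._cycle_graph()
        sol = _solution({"R1": 1.0, "R2": 1.0, "R3": 1.0, "R4": 1.0})
        pruned = network.prune_by_flux(graph, sol)
        assert set(pruned.nodes) == {"a_c", "b_c", "c_c"}
        assert all(d["weight"] == 1.0 for *_, d in pruned.edges(data=True))

    def test_threshold_breaks_cycle(self):
        graph = self._cycle_graph()
        sol = _solution({"R1": 1.0, "R2": 1e-7, "R3": 1.0, "R4": 1.0})
        pruned = network.prune_by_flux(graph, sol)
        assert pruned.number_of_edges() == 0

    def test_idempotent(self):
        graph = self._cycle_graph()
        sol = _solution({"R1": 1.0, "R2": 0.5, "R3": 2.0, "R4": 1.0})
        once = network.prune_by_flux(graph, sol)
        twice = network.prune_by_flux(once, sol)
        assert set(once.edges(keys=True)) == set(twice.edges(keys=True))


class TestCentrality:
    def test_directed_three_cycle(self):
        graph = nx.MultiDiGraph([("a", "b"), ("b", "c"), ("c", "a")])
        table = network.centrality(graph)
        assert np.allclose(table["degree_norm"], 1.0)
        # Each node lies on the single shortest path between the other two:
        # raw betweenness 1, normalized 1 / ((n-1)(n-2)) = 0.5.
        assert np.allclose(table["betweenness_norm"], 0.5)

    def test_star_center(self):
        k = 5
        graph = nx.MultiDiGraph([("hub", f"x{i}") for i in range(k)])
        table = network.centrality(graph)
        assert table.loc["hub", "degree_norm"] == pytest.approx(1.0)
        assert np.allclose(table["betweenness_norm"], 0.0)

    def test_two_nodes_betweenness_zero(self):
        table = network.centrality(nx.MultiDiGraph([("a", "b")]))
        assert np.allclose(table["betweenness_norm"], 0.0)

    def test_bounds_hold_with_reciprocal_edges(self):
        graph = nx.MultiDiGraph()
        for u, v in [("a", "b"), ("b", "a"), ("b", "c"), ("c", "b"), ("c", "a")]:
            graph.add_edge(u, v)
        table = network.centrality(graph)
        assert ((table >= 0) & (table <= 1)).all().all()

    def test_matches_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            density = rng.uniform(0.15, 0.5)
            graph = nx.MultiDiGraph()
            graph.add_nodes_from(range(n))
            for u in range(n):
                for v in range(n):
                    if u != v and rng.random() < density:
                        graph.add_edge(u, v)
            expected = brute_force_betweenness(
                graph.nodes, set(nx.DiGraph(graph).edges))
            table = network.centrality(graph)
            for node in graph.nodes:
                assert table.loc[node, "betweenness_norm"] == pytest.approx(
                    expected[node], abs=1e-9)


class TestFindHubs:
    def _table(self, values):
        return pd.DataFrame(values, columns=["degree_norm", "betweenness_norm"],
                            index=pd.Index([f"m{i}_c" for i in range(len(values))],
                                           name="metabolite"))

    def test_dominant_metabolite_is_hub(self):
        table = self._table([[1.0, 1.0], [0.1, 0.1], [0.2, 0.05], [0.15, 0.2]])
        assert "m0_c" in network.find_hubs([table], quantile=0.9)

    def test_uniform_centralities_all_tie(self):
        table = self._table([[0.5, 0.5]] * 4)
        assert network.find_hubs([table], quantile=0.95) == {
            "m0_c", "m1_c", "m2_c", "m3_c"}

    def test_either_metric_qualifies(self):
        table = self._table([[1.0, 0.0], [0.0, 1.0], [0.1, 0.1], [0.1, 0.1]])
        hubs = network.find_hubs([table], quantile=0.9)
        assert {"m0_c", "m1_c"} <= hubs

    def test_precursor_intersection(self):
        table = pd.DataFrame(
            [[1.0, 1.0], [0.9, 0.9], [0.1, 0.1]],
            columns=["degree_norm", "betweenness_norm"],
            index=pd.Index(["pyr_c", "junk_c", "akg_c"], name="metabolite"))
        hubs = network.find_hubs([table], quantile=0.5,
                                 precursors=network.precursor_metabolites())
        assert hubs == {"pyr_c"}  # junk above quantile but not a precursor

    def test_central_carbon_toy_ranks_hubs_first(self):
        # Fixture built so pyruvate and acetyl-CoA have strictly higher
        # degree than the peripheral metabolites.
        model = build_model("toy", "R1", [
            ("R1", {"glc_D_c": -1.0, "pyr_c": 1.0}, 0.0, DEFAULT_BOUND),
            ("R2", {"lac_L_c": -1.0, "pyr_c": 1.0}, 0.0, DEFAULT_BOUND),
            ("R3", {"pyr_c": -1.0, "accoa_c": 1.0}, -DEFAULT_BOUND, DEFAULT_BOUND),
            ("R4", {"accoa_c": -1.0, "but_c": 1.0}, 0.0, DEFAULT_BOUND),
            ("R5", {"accoa_c": -1.0, "etoh_c": 1.0}, 0.0, DEFAULT_BOUND),
        ])
        table = network.centrality(network.build_graph(model))
        peripheral = ["glc_D_c", "lac_L_c", "but_c", "etoh_c"]
        for hub in ("pyr_c", "accoa_c"):
            assert all(table.loc[hub, "degree_norm"] > table.loc[p, "degree_norm"]
                       for p in peripheral)


def test_edge_list_export(tmp_path):
    graph = nx.MultiDiGraph()
    graph.add_edge("a", "b", reaction="R1", weight=2.0)
    path = tmp_path / "edges.tsv"
    network.write_edge_list(graph, path)
    assert path.read_text() == "from\tto\treaction\tweight\na\tb\tR1\t2\n"
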