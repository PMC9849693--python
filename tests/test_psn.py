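"""Protein structure networks, persistence thresholds, hubs and CR."""

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camryr import synthetic
from camryr.psn import (
    InteractionRecord,
    PersistenceMatrix,
    build_psn,
    cr_index,
    delta_degree,
    ef_hand_cr,
    hubs,
    persistence_from_records,
    report_hubs,
    select_pt,
    shortest_paths,
)


def pm(pairs, cls="hydrophobic", n_frames=100):
    """PersistenceMatrix from a {(i, j): persistence} dict."""
    return PersistenceMatrix(
        values={cls: {tuple(sorted(p)): v for p, v in pairs.items()}},
        n_frames=n_frames)


def exhaustive_shortest(graph, x, y):
    """Brute-force oracle: enumerate every simple path, keep the shortest."""
    best_len, count = math.inf, 0
    for path in nx.all_simple_paths(graph, x, y):
        hops = len(path) - 1
        if hops < best_len:
            best_len, count = hops, 1
        elif hops == best_len:
            count += 1
    return (best_len, count) if count else (math.inf, 0)


class TestPersistence:
    def test_always_present_pair(self):
        records = [InteractionRecord(f, "A1", "A2", "hbond") for f in range(10)]
        mat = persistence_from_records(records, 10)
        assert mat.values["hbond"][("A1", "A2")] == 1.0

    def test_absent_pair_not_reported(self):
        mat = persistence_from_records([], 10)
        assert mat.merged() == {}

    def test_fractional_occupancy(self):
        rng = np.random.default_rng(0)
        frames = rng.choice(100, size=37, replace=False)
        records = [InteractionRecord(int(f), "A1", "B2", "hydrophobic")
                   for f in frames]
        mat = persistence_from_records(records, 100)
        assert mat.values["hydrophobic"][("A1", "B2")] == pytest.approx(0.37)

    def test_duplicates_in_same_frame_count_once(self):
        records = [InteractionRecord(0, "A1", "A2", "hbond")] * 3
        mat = persistence_from_records(records, 4)
        assert mat.values["hbond"][("A1", "A2")] == pytest.approx(0.25)

    def test_frame_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            persistence_from_records(
                [InteractionRecord(5, "A1", "A2", "hbond")], 5)

    def test_canonical_pair_storage(self):
        rec = InteractionRecord(0, "B9", "A1", "hbond")
        assert rec.pair == ("A1", "B9")


class TestSelectPt:
    def test_planted_transition_found(self):
        # dense 6-node cluster whose edges all persist at ~0.45
        cluster = {(f"H{i}", f"H{j}"): 0.45 for i, j in combinations(range(6), 2)}
        cluster[("H0", "Z1")] = 0.9  # a couple of stronger stragglers
        cluster[("Z1", "Z2")] = 0.9
        grid = np.round(np.arange(0.05, 1.0, 0.05), 10)
        pt = select_pt(pm(cluster), grid)
        assert abs(pt - 0.45) <= 0.05

    def test_flat_curve_falls_back(self):
        cluster = {(f"H{i}", f"H{i + 1}"): 1.0 for i in range(5)}
        with pytest.warns(RuntimeWarning, match="flat"):
            assert select_pt(pm(cluster)) == 0.2

    def test_empty_network_falls_back(self):
        with pytest.warns(RuntimeWarning, match="empty"):
            assert select_pt(pm({})) == 0.2

    def test_two_node_network_degenerate(self):
        with pytest.warns(RuntimeWarning):
            assert select_pt(pm({("A1", "A2"): 1.0})) == 0.2


class TestBuildPsn:
    def test_threshold_filter_matches_oracle(self):
        pairs = {("A1", "A2"): 0.1, ("A2", "A3"): 0.25, ("A3", "A4"): 0.4,
                 ("A1", "A4"): 0.2, ("A2", "A5"): 0.15}
        graph = build_psn(pm(pairs), 0.2)
        expected = {tuple(sorted(p)) for p, v in pairs.items() if v >= 0.2}
        assert {tuple(sorted(e)) for e in graph.graph.edges} == expected

    def test_low_threshold_keeps_support(self):
        pairs = {("A1", "A2"): 0.01, ("A2", "A3"): 0.9}
        graph = build_psn(pm(pairs), 0.005)
        assert graph.graph.number_of_edges() == 2

    def test_threshold_above_max_empties_graph(self):
        pairs = {("A1", "A2"): 0.5, ("A2", "A3"): 0.7}
        graph = build_psn(pm(pairs), 0.75)
        assert graph.graph.number_of_edges() == 0

    def test_classes_merge_by_max(self):
        mat = PersistenceMatrix(
            values={"hbond": {("A1", "A2"): 0.3},
                    "hydrophobic": {("A1", "A2"): 0.6}},
            n_frames=10)
        graph = build_psn(mat, 0.5)
        assert graph.graph.edges[("A1", "A2")]["persistence"] == 0.6

    @settings(derandomize=True, max_examples=30)
    @given(pt_lo=st.floats(0.05, 0.45), pt_hi=st.floats(0.5, 0.95),
           seed=st.integers(0, 1000))
    def test_raising_pt_never_adds_edges(self, pt_lo, pt_hi, seed):
        rng = np.random.default_rng(seed)
        pairs = {(f"A{i}", f"A{j}"): float(rng.random())
                 for i, j in combinations(range(8), 2) if rng.random() < 0.5}
        lo = build_psn(pm(pairs), pt_lo).graph
        hi = build_psn(pm(pairs), pt_hi).graph
        assert set(hi.edges) <= set(lo.edges)


class TestHubs:
    def test_star_graph_center(self):
        pairs = {("C0", f"L{i}"): 0.9 for i in range(1, 7)}
        graph = build_psn(pm(pairs), 0.5)
        hub_table = hubs(graph, min_degree=4)
        assert hub_table == {"C0": 6}
        assert report_hubs([graph], report_degree=6) == {"C0"}

    def test_empty_graph_no_hubs(self):
        graph = build_psn(pm({("A1", "A2"): 0.1}), 0.5)
        assert hubs(graph) == {}

    def test_degrees_match_adjacency_row_sums(self):
        rng = np.random.default_rng(5)
        nodes = [f"A{i}" for i in range(10)]
        pairs = {(a, b): 0.9 for a, b in combinations(nodes, 2)
                 if rng.random() < 0.3}
        graph = build_psn(pm(pairs), 0.5)
        adj = nx.to_numpy_array(graph.graph, nodelist=sorted(graph.graph.nodes))
        for node, row in zip(sorted(graph.graph.nodes), adj):
            assert graph.graph.degree(node) == int(row.sum())


class TestDeltaDegree:
    def test_identical_graphs_zero(self):
        pairs = {("A1", "A2"): 0.9, ("A2", "A3"): 0.9}
        g = build_psn(pm(pairs), 0.5)
        per_node, total = delta_degree(g, g)
        assert total == 0 and all(v == 0 for v in per_node.values())

    def test_one_extra_edge_handshake(self):
        base = {("A1", "A2"): 0.9}
        extra = {("A1", "A2"): 0.9, ("A2", "A3"): 0.9}
        gv = build_psn(pm(extra), 0.5)
        gw = build_psn(pm(base), 0.5, extra_nodes=["A3"])
        per_node, total = delta_degree(gv, gw)
        assert per_node["A2"] == 1 and per_node["A3"] == 1
        assert total == 2

    def test_planted_rewiring_totals(self):
        rng = np.random.default_rng(6)
        nodes = [f"A{i}" for i in range(8)]
        wt_pairs = {(a, b): 0.9 for a, b in combinations(nodes, 2)
                    if rng.random() < 0.4}
        # rewire: drop 2 edges, add 2 new ones
        dropped = list(wt_pairs)[:2]
        var_pairs = {k: v for k, v in wt_pairs.items() if k not in dropped}
        for cand in combinations(nodes, 2):
            key = tuple(sorted(cand))
            if key not in wt_pairs and len(var_pairs) < len(wt_pairs) + 0:
                var_pairs[key] = 0.9
        gv = build_psn(pm(var_pairs), 0.5, extra_nodes=nodes)
        gw = build_psn(pm(wt_pairs), 0.5, extra_nodes=nodes)
        per_node, total = delta_degree(gv, gw, nodes)
        brute = {n: (sum(n in p for p in var_pairs)
                     - sum(n in p for p in wt_pairs)) for n in nodes}
        assert per_node == brute
        assert total == sum(brute.values())

    def test_missing_node_counts_zero_with_notice(self):
        gv = build_psn(pm({("A1", "A2"): 0.9}), 0.5)
        gw = build_psn(pm({("A1", "A3"): 0.9}), 0.5)
        with pytest.warns(RuntimeWarning, match="absent"):
            per_node, _ = delta_degree(gv, gw, ["A2"])
        assert per_node["A2"] == 1


class TestShortestPaths:
    def test_adjacent_nodes(self):
        g = build_psn(pm({("A1", "A2"): 0.9}), 0.5)
        l, n, paths = shortest_paths(g, "A1", "A2")
        assert (l, n) == (1, 1) and paths == [["A1", "A2"]]

    def test_four_cycle_opposite_corners(self):
        pairs = {("A1", "A2"): 0.9, ("A2", "A3"): 0.9,
                 ("A3", "A4"): 0.9, ("A1", "A4"): 0.9}
        g = build_psn(pm(pairs), 0.5)
        l, n, _ = shortest_paths(g, "A1", "A3")
        assert (l, n) == (2, 2)

    def test_disconnected_pair(self):
        g = build_psn(pm({("A1", "A2"): 0.9, ("B1", "B2"): 0.9}), 0.5)
        l, n, paths = shortest_paths(g, "A1", "B1")
        assert l == math.inf and n == 0 and paths == []

    def test_unknown_node_rejected(self):
        g = build_psn(pm({("A1", "A2"): 0.9}), 0.5)
        with pytest.raises(KeyError):
            shortest_paths(g, "A1", "Z9")

    def test_matches_exhaustive_oracle_on_random_graphs(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_nodes = int(rng.integers(5, 13))
            nodes = [f"N{i}" for i in range(n_nodes)]
            pairs = {(a, b): 0.9 for a, b in combinations(nodes, 2)
                     if rng.random() < 0.3}
            g = build_psn(pm(pairs), 0.5, extra_nodes=nodes)
            x, y = rng.choice(nodes, size=2, replace=False)
            l, n, _ = shortest_paths(g, str(x), str(y))
            assert (l, n) == exhaustive_shortest(g.graph, str(x), str(y))


class TestCRIndex:
    def test_disconnected_pair_zero(self):
        g = build_psn(pm({("A1", "A2"): 0.9, ("B1", "B2"): 0.9}), 0.5)
        assert cr_index(g, "A1", "B1") == 0.0

    def test_both_forms_on_single_path(self):
        pairs = {("A1", "A2"): 0.9, ("A2", "A3"): 0.9, ("A3", "A4"): 0.9}
        g = build_psn(pm(pairs), 0.2)
        assert cr_index(g, "A1", "A4") == pytest.approx(1 * 0.2 / 3)
        assert cr_index(g, "A1", "A4", form="n_pt_pow_l") == pytest.approx(0.2 ** 3)

    def test_four_cycle_default_form(self):
        pairs = {("A1", "A2"): 0.9, ("A2", "A3"): 0.9,
                 ("A3", "A4"): 0.9, ("A1", "A4"): 0.9}
        g = build_psn(pm(pairs), 0.3)
        assert cr_index(g, "A1", "A3") == pytest.approx(2 * 0.3 / 2)

    def test_same_node_rejected(self):
        g = build_psn(pm({("A1", "A2"): 0.9}), 0.5)
        with pytest.raises(ValueError):
            cr_index(g, "A1", "A1")


class TestEFHandCR:
    def test_disconnected_ef_pair_non_robust(self):
        records, _ = synthetic.gen_ef_network_records(seed=0,
                                                      break_ef1_ef3=True)
        mat = persistence_from_records(records, 100)
        g = build_psn(mat, 0.2)
        cr = ef_hand_cr(g)
        assert not cr.is_robust("EF1", "EF3")
        assert cr.pair("EF1", "EF3") < 0.1

    def test_planted_route_recovered(self):
        records, _ = synthetic.gen_ef_network_records(seed=1)
        mat = persistence_from_records(records, 100)
        cr = ef_hand_cr(build_psn(mat, 0.2))
        assert cr.is_robust("EF3", "EF4")
        assert cr.is_robust("EF1", "EF3")

    def test_matrix_is_symmetric(self):
        records, _ = synthetic.gen_ef_network_records(seed=2)
        mat = persistence_from_records(records, 100)
        cr = ef_hand_cr(build_psn(mat, 0.2))
        assert np.allclose(cr.values.to_numpy(), cr.values.to_numpy().T)

    def test_missing_representative_rejected(self):
        g = build_psn(pm({("A1", "A2"): 0.9}), 0.5)
        with pytest.raises(KeyError):
            ef_hand_cr(g)
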