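"""Solution-graph aggregation and the minmax reduction."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from idss import (
    SearchConfig,
    aggregate,
    compute_frequencies,
    edge_weight,
    idss_search,
    minmax,
    spanning_weight,
)
from idss.graphs import write_dot, write_graphml
from idss.search import SolutionSet
from idss.types import AssemblageCounts


def _solution_set(orders, config=None):
    return SolutionSet(
        orders=[tuple(o) for o in orders],
        certificates=[None] * len(orders),
        config=config or SearchConfig(seed=0),
    )


@pytest.fixture
def toy_freqs():
    c = AssemblageCounts(
        ("A", "B", "C", "D"),
        ("t1", "t2", "t3"),
        [[80, 10, 10], [60, 30, 10], [40, 40, 20], [20, 50, 30]],
    )
    return compute_frequencies(c)


class TestEdgeWeight:
    def test_identical_rows_zero(self):
        c = AssemblageCounts(
            ("A", "B"), ("x", "y", "z"), [[10, 10, 10], [20, 20, 20]]
        )
        f = compute_frequencies(c)
        assert edge_weight("A", "B", f, "euclidean") == 0.0
        assert edge_weight("A", "B", f, "summed_l1") == 0.0

    def test_disjoint_unit_rows(self):
        c = AssemblageCounts(
            ("A", "B"), ("x", "y", "z"), [[100, 0, 0], [0, 100, 0]]
        )
        f = compute_frequencies(c)
        assert edge_weight("A", "B", f, "euclidean") == pytest.approx(math.sqrt(2))
        assert edge_weight("A", "B", f, "summed_l1") == pytest.approx(2.0)

    def test_pfg_pair_hand_computed(self, pfg, pfg_freqs):
        # independent recomputation from the raw counts
        df = pfg.to_dataframe()
        a = (df.loc["13-N-5"] / df.loc["13-N-5"].sum()).to_numpy()
        b = (df.loc["13-N-4"] / df.loc["13-N-4"].sum()).to_numpy()
        assert edge_weight("13-N-5", "13-N-4", pfg_freqs, "euclidean") == (
            pytest.approx(float(np.sqrt(((a - b) ** 2).sum())), abs=1e-12)
        )
        assert edge_weight("13-N-5", "13-N-4", pfg_freqs, "summed_l1") == (
            pytest.approx(float(np.abs(a - b).sum()), abs=1e-12)
        )

    def test_symmetry_and_rejections(self, pfg_freqs):
        assert edge_weight("13-N-5", "13-N-4", pfg_freqs) == edge_weight(
            "13-N-4", "13-N-5", pfg_freqs
        )
        with pytest.raises(ValueError):
            edge_weight("13-N-5", "13-N-5", pfg_freqs)
        with pytest.raises(ValueError):
            edge_weight("13-N-5", "13-N-4", pfg_freqs, metric="cosine")


class TestAggregate:
    def test_single_solution_path(self, toy_freqs):
        g = aggregate(_solution_set([("A", "B", "C")]), toy_freqs)
        assert sorted(g.nodes) == ["A", "B", "C"]
        assert sorted(map(sorted, g.edges)) == [["A", "B"], ["B", "C"]]

    def test_union_with_provenance(self, toy_freqs):
        g = aggregate(
            _solution_set([("A", "B", "C"), ("C", "B", "D")]), toy_freqs
        )
        assert sorted(map(sorted, g.edges)) == [["A", "B"], ["B", "C"], ["B", "D"]]
        assert g.edges["B", "C"]["solutions"] == [0, 1]
        assert g.edges["A", "B"]["solutions"] == [0]

    def test_empty_solution_set_warns(self, toy_freqs):
        with pytest.warns(UserWarning):
            g = aggregate(_solution_set([]), toy_freqs)
        assert g.number_of_nodes() == 0

    def test_weights_match_metric(self, toy_freqs):
        g = aggregate(_solution_set([("A", "B", "C")]), toy_freqs, "summed_l1")
        assert g.edges["A", "B"]["weight"] == pytest.approx(
            edge_weight("A", "B", toy_freqs, "summed_l1")
        )


def _graph(edges):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w, solutions=[0])
    return g


def _brute_force_msf_weight(g):
    """Minimum spanning forest weight by exhaustive search over edge
    subsets (independent of any MST algorithm)."""
    best = math.inf
    edges = list(g.edges(data="weight"))
    n_components_target = nx.number_connected_components(g)
    need = g.number_of_nodes() - n_components_target
    for subset in itertools.combinations(edges, need):
        h = nx.Graph()
        h.add_nodes_from(g.nodes)
        h.add_weighted_edges_from(subset)
        if nx.number_connected_components(h) == n_components_target:
            best = min(best, sum(w for _, _, w in subset))
    return best


class TestMinmax:
    def test_single_path_unchanged(self, toy_freqs):
        agg = aggregate(_solution_set([("A", "B", "C", "D")]), toy_freqs)
        mm = minmax(agg)
        assert sorted(map(sorted, mm.edges)) == sorted(map(sorted, agg.edges))

    def test_triangle_with_tie_keeps_both_light_edges(self):
        g = _graph([("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 5.0)])
        mm = minmax(g)
        assert sorted(map(sorted, mm.edges)) == [["A", "B"], ["B", "C"]]

    def test_triangle_distinct_weights_is_spanning_tree(self):
        g = _graph([("A", "B", 1.0), ("B", "C", 2.0), ("A", "C", 3.0)])
        mm = minmax(g)
        assert sorted(map(sorted, mm.edges)) == [["A", "B"], ["B", "C"]]
        assert spanning_weight(g) == pytest.approx(3.0)

    def test_tie_at_joining_weight_retained(self):
        # C first connects at weight 2; the second weight-2 edge touching C
        # is kept as a tie even though it closes a cycle
        g = _graph([("A", "B", 1.0), ("B", "C", 2.0), ("A", "C", 2.0)])
        mm = minmax(g)
        assert sorted(map(sorted, mm.edges)) == [["A", "B"], ["A", "C"], ["B", "C"]]
        ties = [e for e in mm.edges if mm.edges[e]["tie"]]
        assert len(ties) == 1

    def test_minmax_edges_subset_of_aggregate(self, pfg, raw_config,
                                              pfg_freqs):
        sols = idss_search(pfg, raw_config)
        agg = aggregate(sols, pfg_freqs)
        mm = minmax(agg)
        assert set(mm.nodes) == set(agg.nodes)
        for e in mm.edges:
            assert agg.has_edge(*e)

    def test_skeleton_weight_equals_bruteforce_msf(self):
        rng = np.random.default_rng(5)
        for trial in range(6):
            n = int(rng.integers(4, 8))
            g = nx.Graph()
            g.add_nodes_from(range(n))
            for u, v in itertools.combinations(range(n), 2):
                if rng.random() < 0.6:
                    g.add_edge(str(u), str(v), weight=float(rng.integers(1, 9)),
                               solutions=[0])
            g.remove_nodes_from(list(range(n)))
            if g.number_of_edges() < 3:
                continue
            assert spanning_weight(g) == pytest.approx(_brute_force_msf_weight(g))

    def test_disconnected_aggregate_gives_forest(self):
        g = _graph([("A", "B", 1.0), ("C", "D", 2.0)])
        mm = minmax(g)
        assert nx.number_connected_components(mm) == 2
        assert mm.number_of_edges() == 2


class TestWriters:
    def test_graphml_reproducible_and_readable(self, pfg, raw_config,
                                               pfg_freqs, tmp_path):
        sols = idss_search(pfg, raw_config)
        mm = minmax(aggregate(sols, pfg_freqs))
        p1, p2 = tmp_path / "a.graphml", tmp_path / "b.graphml"
        write_graphml(mm, p1)
        write_graphml(mm, p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = nx.read_graphml(p1)
        assert back.number_of_nodes() == mm.number_of_nodes()
        assert back.number_of_edges() == mm.number_of_edges()

    def test_dot_output_parses_structurally(self, toy_freqs, tmp_path):
        agg = aggregate(_solution_set([("A", "B", "C")]), toy_freqs)
        p = tmp_path / "g.dot"
        write_dot(agg, p)
        text = p.read_text()
        assert text.startswith("graph")
        assert '"A" -- "B"' in text
        assert text.count("--") == 2
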