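"""Full graphlet counting, clustering coefficients and incremental deltas."""

from math import comb

import networkx as nx
import numpy as np
import pytest

from graip.catalog import graphlet_types
from graip.counting import (
    clustering_global,
    clustering_local,
    count_all,
    delta_for_edge,
    delta_for_node,
    enumerate_connected_sets,
)

TYPES = graphlet_types(5)
CLIQUE_INDEX = {3: 1, 4: 7, 5: 28}  # M2, M8, M29


class TestCountAll:
    @pytest.mark.parametrize("n,expected", [(10, 252), (9, 126)])
    def test_five_clique_counts_in_complete_graphs(self, n, expected):
        counts = count_all(nx.complete_graph(n), 5)
        assert counts[28] == expected

    def test_triangle_graph(self):
        counts = count_all(nx.complete_graph(3), 5)
        assert counts[1] == 1
        assert counts.sum() == 1

    def test_path_graph(self):
        counts = count_all(nx.path_graph(3), 5)
        assert counts[0] == 1
        assert counts.sum() == 1

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_complete_graph_clique_counts_binomial(self, n):
        counts = count_all(nx.complete_graph(n), 5)
        for k, idx in CLIQUE_INDEX.items():
            assert counts[idx] == comb(n, k)

    def test_total_matches_connected_subgraph_enumeration(self):
        # independent oracle: all node subsets, connectivity by networkx
        from itertools import combinations

        g = nx.gnm_random_graph(12, 20, seed=4)
        counts = count_all(g, 5)
        total = 0
        for k in (3, 4, 5):
            for sub in combinations(g.nodes, k):
                if nx.is_connected(g.subgraph(sub)):
                    total += 1
        assert counts.sum() == total


class TestClustering:
    def test_global_examples(self):
        assert clustering_global(count_all(nx.complete_graph(3), 3)) == 1.0
        assert clustering_global(count_all(nx.path_graph(3), 3)) == 0.0
        assert clustering_global(count_all(nx.complete_graph(4), 3)) == 1.0
        assert clustering_global(np.zeros(2)) == 0.0

    def test_global_matches_networkx_transitivity(self):
        g = nx.gnm_random_graph(30, 70, seed=2)
        assert clustering_global(count_all(g, 3)) == pytest.approx(
            nx.transitivity(g)
        )

    def test_local_examples(self):
        star = nx.star_graph(4)
        assert clustering_local(star, 0) == 0.0
        assert clustering_local(star, 1) == 0.0  # degree-1 convention
        assert clustering_local(nx.complete_graph(3), 0) == 1.0

    def test_local_matches_networkx(self):
        g = nx.gnm_random_graph(25, 60, seed=9)
        for v in g.nodes:
            assert clustering_local(g, v) == pytest.approx(nx.clustering(g, v))

    def test_local_unknown_node(self):
        with pytest.raises(KeyError):
            clustering_local(nx.path_graph(3), 99)


class TestEnumeration:
    def test_star_hub_three_sets(self):
        star = nx.star_graph(4)
        sets = list(enumerate_connected_sets(star, (0,), 3, min_order=3))
        assert len(sets) == 6  # hub + any 2 of 4 leaves

    def test_anchored_pair_on_triangle(self):
        g = nx.complete_graph(3)
        sets = {frozenset(s) for s in enumerate_connected_sets(g, (0, 1), 3)}
        assert sets == {frozenset({0, 1}), frozenset({0, 1, 2})}

    def test_duplicate_free_random_trials(self, rng):
        for _ in range(50):
            g = nx.gnm_random_graph(15, int(rng.integers(15, 40)), seed=int(rng.integers(10_000)))
            anchor = int(rng.integers(15))
            sets = [frozenset(s) for s in enumerate_connected_sets(g, (anchor,), 4)]
            assert len(sets) == len(set(sets))

    def test_yields_every_connected_superset(self):
        from itertools import combinations

        g = nx.gnm_random_graph(10, 18, seed=6)
        u = 0
        got = {frozenset(s) for s in enumerate_connected_sets(g, (u,), 4)}
        want = set()
        for k in (1, 2, 3, 4):
            for sub in combinations(g.nodes, k):
                if u in sub and nx.is_connected(g.subgraph(sub)):
                    want.add(frozenset(sub))
        assert got == want


def random_edit_sequence(g, rng, n_edits, n_g):
    """Apply random single edge/node edits, checking each delta against a
    full recount (the independent oracle)."""
    counts = count_all(g, n_g)
    next_node = max(g.nodes) + 1
    for _ in range(n_edits):
        nodes = sorted(g.nodes)
        kind = rng.random()
        if kind < 0.35 and len(nodes) >= 2:
            i, j = rng.choice(len(nodes), 2, replace=False)
            u, v = nodes[i], nodes[j]
            adding = not g.has_edge(u, v)
            delta = delta_for_edge(g, u, v, adding, n_g)
            if adding:
                g.add_edge(u, v)
            else:
                g.remove_edge(u, v)
        elif kind < 0.7 and g.number_of_edges() > 0:
            edges = sorted(map(tuple, map(sorted, g.edges)))
            u, v = edges[rng.integers(len(edges))]
            delta = delta_for_edge(g, u, v, False, n_g)
            g.remove_edge(u, v)
        elif kind < 0.85 and len(nodes) > 5:
            u = nodes[rng.integers(len(nodes))]
            incident = [(u, w) for w in g.neighbors(u)]
            delta = delta_for_node(g, u, incident, False, n_g)
            g.remove_node(u)
        else:
            u = next_node
            next_node += 1
            k = int(rng.integers(0, min(4, len(nodes)) + 1))
            nbrs = rng.choice(len(nodes), size=k, replace=False) if k else []
            incident = [(u, nodes[i]) for i in nbrs]
            delta = delta_for_node(g, u, incident, True, n_g)
            g.add_node(u)
            g.add_edges_from(incident)
        counts = counts + delta
        assert np.all(counts >= 0)
        recount = count_all(g, n_g)
        np.testing.assert_array_equal(counts, recount)


class TestIncrementalDeltas:
    def test_closing_a_triangle(self):
        g = nx.path_graph(3)
        delta = delta_for_edge(g, 0, 2, True, 5)
        assert delta[0] == -1 and delta[1] == +1
        assert delta.sum() == 0

    def test_edge_between_isolated_nodes(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1])
        assert not delta_for_edge(g, 0, 1, True, 5).any()

    def test_removing_isolated_node(self):
        g = nx.path_graph(3)
        g.add_node(9)
        assert not delta_for_node(g, 9, [], False, 5).any()

    def test_growing_a_five_clique(self):
        g = nx.complete_graph(4)
        delta = delta_for_node(g, 9, [(9, i) for i in range(4)], True, 5)
        assert delta[28] == 1  # exactly one new 5-clique

    def test_precondition_violations(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            delta_for_edge(g, 0, 1, True, 4)  # already present
        with pytest.raises(ValueError):
            delta_for_edge(g, 0, 2, False, 4)  # not present
        with pytest.raises(ValueError):
            delta_for_node(g, 0, [], False, 4)  # wrong incident edges
        with pytest.raises(ValueError):
            delta_for_node(g, 1, [(1, 0)], True, 4)  # already present

    @pytest.mark.parametrize(
        "n_g,n,m,edits", [(3, 50, 100, 40), (4, 40, 80, 30), (5, 30, 55, 20)]
    )
    def test_edit_sequences_match_full_recounts(self, n_g, n, m, edits):
        g = nx.gnm_random_graph(n, m, seed=n_g)
        rng = np.random.default_rng(1000 + n_g)
        random_edit_sequence(g, rng, edits, n_g)
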