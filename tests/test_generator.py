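"""The incremental generator: gates, proposals, cost, bounds, full runs."""

import math

import networkx as nx
import numpy as np
import pytest

from graip.counting import count_all
from graip.generator import (
    CostBreakdown,
    DegenerateTargetError,
    GeneratorParams,
    add_node_proposal,
    cost,
    edge_deviation,
    generate,
    logistic_gate,
    p_neighbor,
    within_bounds,
    _binned_fractions,
)
from graip.stats import sample_statistics
from graip.graphs import UncertainGraph


class TestLogisticGate:
    def test_balance_point(self):
        assert logistic_gate(0.0) == 0.5

    def test_growing_phase_gate_near_zero(self):
        assert logistic_gate(-50.0) < 1e-20

    def test_unit_deviation(self):
        assert logistic_gate(1.0) == pytest.approx(1 / (1 + math.exp(-1)))

    def test_extreme_deviations_do_not_overflow(self):
        assert logistic_gate(1e9) == 1.0
        assert logistic_gate(-1e9) == pytest.approx(0.0, abs=1e-300)


class TestEdgeDeviation:
    def _stats(self, er_stats):
        return er_stats

    def test_scaled_balance_point(self, er_stats):
        n = 30
        m = er_stats.E_m * n / er_stats.E_n
        assert edge_deviation(n, m, er_stats) == pytest.approx(0.0, abs=1e-9)

    def test_one_sigma_above(self, er_stats):
        # at n = E_n and m = E_m + s_m the standardized deviation is one
        d = edge_deviation(er_stats.E_n, er_stats.E_m + er_stats.s_m, er_stats)
        assert d == pytest.approx(1.0)

    def test_oversized_graph_pushed_denser(self, er_stats):
        # n twice the target with target edge count: scaled m is half E_m,
        # so the deviation is negative and edge addition favored
        d = edge_deviation(int(2 * er_stats.E_n), int(er_stats.E_m), er_stats)
        assert d < 0


class TestPNeighbor:
    def test_closed_form_inverts_expected_clustering(self):
        k_v, e_nv, cc = 2, 0, 0.5
        p = p_neighbor(k_v, e_nv, cc)
        assert p == pytest.approx(0.75)
        # substituting back gives the target clustering
        cc_expected = 2 * (e_nv + p * k_v) / (k_v * (k_v + 1))
        assert cc_expected == pytest.approx(cc)

    def test_zero_target_clustering(self):
        assert p_neighbor(3, 0, 0.0) == 0.0

    def test_clamped_when_neighborhood_already_dense(self):
        assert p_neighbor(2, 10, 0.1) == 0.0

    def test_clamped_above(self):
        assert p_neighbor(1, 0, 1.0) == 1.0

    def test_degree_zero_anchor_rejected(self):
        with pytest.raises(ValueError):
            p_neighbor(0, 0, 0.5)


class TestAddNodeProposal:
    def test_clique_membership_extends_the_clique(self, rng):
        H = nx.complete_graph(4)
        edges = add_node_proposal(H, 9, 0.0, rng)
        assert sorted(e[1] for e in edges) == [0, 1, 2, 3]

    def test_star_hub_with_zero_clustering_gets_single_edge(self):
        H = nx.star_graph(6)
        rng = np.random.default_rng(0)
        for _ in range(20):
            edges = add_node_proposal(H, 99, 0.0, rng)
            assert len(edges) == 1

    def test_anchor_frequencies_proportional_to_degree(self):
        from scipy import stats as sps

        H = nx.barabasi_albert_graph(20, 2, seed=3)
        rng = np.random.default_rng(42)
        counts = {v: 0 for v in H.nodes}
        trials = 10_000
        for _ in range(trials):
            edges = add_node_proposal(H, 999, 0.0, rng)
            # anchor is the certain neighbor (single edge at cc_bar=0,
            # unless the anchor sits in a clique)
            anchors = [v for _, v in edges]
            if len(anchors) == 1:
                counts[anchors[0]] += 1
        total = sum(counts.values())
        degs = dict(H.degree)
        # restrict to non-clique anchors: BA(20,2) rarely has K4s, but be safe
        expected = np.array([degs[v] for v in counts])
        expected = expected / expected.sum() * total
        observed = np.array(list(counts.values()))
        _, pval = sps.chisquare(observed, expected)
        assert pval > 0.01


class TestCost:
    def test_zero_at_the_target(self, er_stats):
        c = cost(er_stats.E_p.copy(), er_stats.E_c.copy(), er_stats, 2 / 3)
        assert c.total == pytest.approx(0.0, abs=1e-12)
        assert c.cost_p == 0.0 and c.cost_c == 0.0

    def test_graphlet_term_counts_band_widths(self, er_stats):
        # one type at E*(1+f)^2 with all others on target costs 2/|E_c|
        C = er_stats.E_c.copy()
        i = int(np.argmax(er_stats.E_c))
        f = 2 * er_stats.s_c[i] / er_stats.E_c[i]
        C[i] = er_stats.E_c[i] * (1 + f) ** 2
        c = cost(er_stats.E_p.copy(), C, er_stats, 0.0)
        assert c.cost_c == pytest.approx(2 / len(er_stats.E_c))

    def test_inside_band_costs_nothing(self, er_stats):
        C = er_stats.E_c + 1.9 * er_stats.s_c
        c = cost(er_stats.E_p.copy(), C, er_stats, 0.5)
        assert c.cost_c == 0.0

    def test_monotone_in_degree_deviation(self, er_stats):
        P = er_stats.E_p.copy()
        P[0] += 0.1
        P[-1] -= 0.1
        worse = P.copy()
        worse[0] += 0.1
        worse[-1] -= 0.1
        c1 = cost(P, er_stats.E_c.copy(), er_stats, 1.0)
        c2 = cost(worse, er_stats.E_c.copy(), er_stats, 1.0)
        assert 0 < c1.total < c2.total

    def test_zero_count_below_band_is_finite(self, er_stats):
        C = np.zeros_like(er_stats.E_c)
        c = cost(er_stats.E_p.copy(), C, er_stats, 0.0)
        assert np.isfinite(c.total) and c.total > 0


class TestWithinBounds:
    def test_boundary_is_closed(self, er_stats):
        C = er_stats.E_c + 2 * er_stats.s_c
        assert within_bounds(er_stats.E_p.copy(), C, er_stats)

    def test_empty_graph_fails(self, er_stats):
        P = np.zeros_like(er_stats.E_p)
        C = np.zeros(len(er_stats.E_c))
        assert not within_bounds(P, C, er_stats)


class TestGenerate:
    def test_degenerate_target_rejected(self, rng):
        g = UncertainGraph()
        for u, v in [(0, 1), (1, 2), (0, 2)]:
            g.add_edge(u, v, 1.0)
        stats = sample_statistics(g, 20, 3, rng)
        with pytest.raises(DegenerateTargetError):
            generate(stats, GeneratorParams(n_g=3), rng=rng)

    def test_terminates_within_bounds_and_counts_consistent(self, er_stats):
        params = GeneratorParams(n_g=4, max_s=None)
        H = generate(er_stats, params, rng=np.random.default_rng(3), check_every=50)
        C = count_all(H, 4)
        assert within_bounds(_binned_fractions(H, er_stats), C, er_stats)

    def test_same_seed_same_graph(self, er_stats):
        params = GeneratorParams(n_g=4, max_s=2000)
        H1 = generate(er_stats, params, rng=np.random.default_rng(11))
        H2 = generate(er_stats, params, rng=np.random.default_rng(11))
        assert set(H1.nodes) == set(H2.nodes)
        assert set(map(frozenset, H1.edges)) == set(map(frozenset, H2.edges))

    def test_node_add_rate_approaches_one_when_far_below_target(self, er_stats):
        # Eq-6 behavior: deep in the growing phase the gate is ~0 and
        # almost every node step adds
        adds = sum(
            np.random.default_rng(s).random() > logistic_gate((10 - er_stats.E_n) / max(er_stats.s_n, 1e-6))
            for s in range(200)
        )
        assert adds >= 198

    def test_forced_acceptance_after_exact_rejection_streak(self, er_stats, monkeypatch):
        # with an impossible cost function every proposal is rejected, so
        # the first acceptance must occur exactly at the max_rej threshold
        import graip.generator as gen_mod

        accept_steps = []
        real_cost = gen_mod.cost
        calls = {"n": 0}
        real_apply = gen_mod._apply

        def spy_apply(H, kind, payload):
            accept_steps.append(calls["n"])
            return real_apply(H, kind, payload)

        def counting_cost(P, C, stats, w):
            calls["n"] += 1
            b = real_cost(P, C, stats, w)
            # make the candidate (second call of each pair) always worse
            if calls["n"] % 2 == 0:
                return CostBreakdown(b.cost_p, b.cost_c, b.total + 1e6)
            return b

        monkeypatch.setattr(gen_mod, "cost", counting_cost)
        monkeypatch.setattr(gen_mod, "_apply", spy_apply)
        params = GeneratorParams(n_g=3, max_s=40, max_rej=7)
        generate(er_stats, params, rng=np.random.default_rng(5))
        # cost is called twice per proposing step; acceptances happen every
        # max_rej + 1 proposals (7 rejections then a forced acceptance)
        proposal_index = [s // 2 for s in accept_steps]
        gaps = np.diff([0] + proposal_index)
        assert all(gap == 8 for gap in gaps[:3])
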