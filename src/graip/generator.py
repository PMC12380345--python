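"""GRAIP: incremental generation of a random graph whose degree
distribution and graphlet counts fall inside the target envelope.

Starting from a small preferential-attachment seed (20% of the expected
nodes and edges), the generator repeatedly proposes single-edge or
single-node modifications.  Whether a proposal grows or shrinks the graph
is gated by a logistic function of the standardized deviation of the
current order (or scaled size) from the target mean, so the graph is
pushed toward the expected order and density.  A proposal is accepted when
it lowers a two-part cost — a degree-distribution term on reversed
cumulative binned distributions and a logarithmic graphlet-count term —
or unconditionally after ``max_rej`` consecutive rejections, which stops
the search from stalling near the boundary.  Candidate costs are computed
from incrementally updated counts and histograms; the modified graph is
materialized only on acceptance.  Generation stops as soon as every binned
degree fraction and every graphlet count lies within mean +/- 2 stdev of
the target, or after ``max_s`` steps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Hashable

import networkx as nx
import numpy as np

from .counting import count_all, delta_for_edge, delta_for_node
from .graphs import UncertainGraph, _adjust_edge_count
from .stats import TargetStatistics, binned_counts, sample_statistics

__all__ = [
    "GeneratorParams",
    "CostBreakdown",
    "DegenerateTargetError",
    "logistic_gate",
    "edge_deviation",
    "p_neighbor",
    "add_node_proposal",
    "cost",
    "within_bounds",
    "generate",
]

#: floor for zero stdevs of certain targets; keeps the logistic gates
#: defined and turns them into hard step functions
SIGMA_FLOOR = 1e-6

#: attempts at drawing a uniform non-edge before giving up
MAX_NONEDGE_TRIES = 10_000

#: node count above which the exact clique search around an anchor is
#: restricted to the anchor plus its highest-degree neighbors
CLIQUE_NEIGHBORHOOD_CAP = 12


logger = logging.getLogger(__name__)


class DegenerateTargetError(ValueError):
    """Target statistics too small or too degenerate to generate from."""


@dataclass
class GeneratorParams:
    """Tunable knobs of the generator.

    ``S`` Monte-Carlo samples feed the target envelope; ``n_g`` is the
    maximum graphlet order tracked (3-5).  Every ``node_step``-th step
    proposes a node move, others propose edge moves.  ``w`` weighs the
    degree term against the graphlet term in the cost.  ``max_rej`` is the
    forced-acceptance threshold; ``None`` selects round(0.02 * E_m),
    floored at one.  ``seed_fraction`` sizes the seed graph.
    """

    S: int = 10_000
    n_g: int = 5
    max_s: int | None = None
    node_step: int = 5
    w: float = 2.0 / 3.0
    max_rej: int | None = None
    seed_fraction: float = 0.2
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.node_step < 1:
            raise ValueError("node_step must be >= 1")
        if not (0.0 <= self.w <= 1.0):
            raise ValueError("w must lie in [0, 1]")
        if self.max_rej is not None and self.max_rej < 1:
            raise ValueError("max_rej must be >= 1")
        if self.n_g not in (3, 4, 5):
            raise ValueError("n_g must be 3, 4 or 5")


@dataclass
class CostBreakdown:
    cost_p: float
    cost_c: float
    total: float


def logistic_gate(deviation: float) -> float:
    """Logistic gate 1 / (1 + exp(-deviation)).

    The caller adds (a node or edge) when its uniform draw exceeds the
    gate, so a strongly negative deviation (graph too small/sparse) makes
    addition almost certain, and zero deviation makes both moves equally
    likely.
    """
    if deviation >= 0:
        return 1.0 / (1.0 + math.exp(-min(deviation, 700.0)))
    z = math.exp(max(deviation, -700.0))
    return z / (1.0 + z)


def edge_deviation(n: int, m: int, stats: TargetStatistics) -> float:
    """Standardized deviation of the size, scaled to the target order.

    m is rescaled by E_n / n so that a graph whose order is off target is
    not additionally pushed toward the wrong density.
    """
    if n == 0:
        raise ValueError("empty graph has no edge deviation")
    s_m = max(stats.s_m, SIGMA_FLOOR)
    return (m * stats.E_n / n - stats.E_m) / s_m


def p_neighbor(k_v: int, e_nv: int, cc_bar: float) -> float:
    """Probability of wiring the incoming node to each neighbor of the
    anchor, chosen so the anchor's expected local clustering coefficient
    after the insertion equals the target's average ``cc_bar``; clamped
    to [0, 1] since the closed form can exceed either bound.
    """
    if k_v < 1:
        raise ValueError("anchor must have degree >= 1")
    p = (cc_bar * k_v * (k_v + 1) / 2.0 - e_nv) / k_v
    return min(max(p, 0.0), 1.0)


def _largest_clique_with(g: nx.Graph, v: Hashable) -> list:
    """Largest clique containing v, searched in v's closed neighborhood.

    On high-degree anchors the neighborhood is truncated to the
    highest-degree neighbors to keep the exact search cheap; the clique
    rule targets small dense groups, so little is lost.
    """
    nbrs = list(g._adj[v])
    if len(nbrs) + 1 > CLIQUE_NEIGHBORHOOD_CAP:
        nbrs.sort(key=lambda u: g.degree[u], reverse=True)
        nbrs = nbrs[: CLIQUE_NEIGHBORHOOD_CAP - 1]
    sub = g.subgraph([v] + nbrs)
    best = [v]
    for clique in nx.find_cliques(sub):
        if v in clique and len(clique) > len(best):
            best = clique
    return sorted(best)


def add_node_proposal(
    H: nx.Graph, u: Hashable, cc_bar: float, rng: np.random.Generator
) -> list[tuple]:
    """Edge set for a new node ``u`` following the preferential rule.

    An anchor v is drawn with probability proportional to its degree
    (uniformly if all degrees are zero).  If v sits in a clique of order
    at least four, u is wired to every member of the largest clique
    containing v, promoting larger cliques that would otherwise be very
    unlikely to form.  Otherwise the edge (u, v) is always added and each
    neighbor of v is wired independently with :func:`p_neighbor`.
    """
    nodes = sorted(H.nodes)
    if not nodes:
        raise ValueError("cannot anchor a node proposal on an empty graph")
    degrees = np.array([H.degree[x] for x in nodes], dtype=float)
    total = degrees.sum()
    if total == 0:
        v = nodes[rng.integers(len(nodes))]
    else:
        v = nodes[rng.choice(len(nodes), p=degrees / total)]

    clique = _largest_clique_with(H, v)
    if len(clique) >= 4:
        return [(u, c) for c in clique]

    nbrs = sorted(H._adj[v])
    k_v = len(nbrs)
    edges = [(u, v)]
    if k_v >= 1:
        e_nv = sum(
            1 for i in range(k_v) for j in range(i + 1, k_v)
            if H.has_edge(nbrs[i], nbrs[j])
        )
        p_nb = p_neighbor(k_v, e_nv, cc_bar)
        for nv in nbrs:
            if rng.random() < p_nb:
                edges.append((u, nv))
    return edges


def _reverse_cumsum(x: np.ndarray) -> np.ndarray:
    return np.cumsum(x[::-1])[::-1]


def cost(
    P_binned: np.ndarray,
    C: np.ndarray,
    stats: TargetStatistics,
    w: float,
) -> CostBreakdown:
    """Two-part cost of a candidate graph against the target envelope.

    Degree term: mean relative deviation between the reversed cumulative
    binned degree distributions (cumulating from the high-degree side
    avoids penalizing an excess of low-degree nodes that is matched by a
    shortage of high-degree ones — high-degree nodes grow from low-degree
    ones here).  Graphlet term: for each type outside its +/- 2 stdev
    band, the log of C/E in the base that maps the band edge to one, so a
    count a whole band-width beyond the bound costs one unit; types inside
    their band cost nothing.  Several graphlet types can explode
    combinatorially (a clique of order ten holds 252 five-cliques, order
    nine only 126), which a relative-error term would overweight; the
    logarithm keeps such jumps commensurate.
    """
    Pc = _reverse_cumsum(P_binned)
    Epc = _reverse_cumsum(stats.E_p)
    mask = Epc > 0
    cost_p = float(
        np.sum(np.abs(Pc[mask] - Epc[mask]) / Epc[mask]) / len(stats.E_p)
    )

    n_c = len(stats.E_c)
    cost_c = 0.0
    for i in range(n_c):
        E, s, c = stats.E_c[i], stats.s_c[i], float(C[i])
        if E - 2 * s <= c <= E + 2 * s:
            continue
        E_eff = max(E, 0.5)
        f = max(2.0 * s / E_eff, 1e-6)
        if c < E - 2 * s:
            base = max(1.0 - f, 0.01)
            c_arg = c if c > 0 else 0.5
        else:
            base = 1.0 + f
            c_arg = c
        cost_c += math.log(c_arg / E_eff) / math.log(base) / n_c
    return CostBreakdown(cost_p, cost_c, w * cost_p + (1.0 - w) * cost_c)


def within_bounds(
    P_binned: np.ndarray, C: np.ndarray, stats: TargetStatistics, tol: float = 1e-9
) -> bool:
    """Elementwise containment of the binned degree distribution and every
    graphlet count in the closed band mean +/- 2 stdev."""
    lo_p = stats.E_p - 2 * stats.s_p - tol
    hi_p = stats.E_p + 2 * stats.s_p + tol
    if np.any(P_binned < lo_p) or np.any(P_binned > hi_p):
        return False
    lo_c = stats.E_c - 2 * stats.s_c - tol
    hi_c = stats.E_c + 2 * stats.s_c + tol
    return bool(np.all((C >= lo_c) & (C <= hi_c)))


def _seed_graph(stats: TargetStatistics, frac: float, rng: np.random.Generator) -> nx.Graph:
    """Preferential-attachment seed with round(frac * E_n) nodes and
    round(frac * E_m) edges."""
    n0 = max(3, int(round(frac * stats.E_n)))
    m0 = max(2, int(round(frac * stats.E_m)))
    attach = max(1, int(round(stats.E_m / stats.E_n)))
    attach = min(attach, n0 - 1)
    H = nx.barabasi_albert_graph(n0, attach, seed=int(rng.integers(2**31)))
    _adjust_edge_count(H, m0, rng)
    return H


def _binned_fractions(H: nx.Graph, stats: TargetStatistics) -> np.ndarray:
    n = H.number_of_nodes()
    if n == 0:
        return np.zeros(stats.bins.n_bins)
    return binned_counts((d for _, d in H.degree), stats.bins) / n


def generate(
    target: UncertainGraph | TargetStatistics,
    params: GeneratorParams | None = None,
    rng: np.random.Generator | None = None,
    check_every: int | None = None,
    initial_graph: nx.Graph | None = None,
    stop_on_bounds: bool = True,
) -> nx.Graph:
    """Generate one deterministic graph inside the target envelope.

    ``target`` is either an uncertain graph (sampled here with
    ``params.S`` worlds) or precomputed :class:`TargetStatistics` (the
    sampling step is the expensive one and worth caching across runs).
    With ``max_s = None`` the loop runs until the bounds are met.  The RNG
    draw order per step is fixed (gate first, then proposal draws), so a
    seeded run is fully reproducible.  ``check_every`` asserts, every that
    many accepted moves, that the incrementally maintained count vector
    still equals a full recount (debugging aid).

    ``initial_graph`` replaces the preferential-attachment seed (it is
    copied, not mutated); with ``stop_on_bounds=False`` the loop ignores
    the envelope stopping rule and always runs ``max_s`` steps — useful to
    randomize further after a small sparse target was met in few moves.
    """
    params = params or GeneratorParams()
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    if isinstance(target, UncertainGraph):
        stats = sample_statistics(target, params.S, params.n_g, rng)
    else:
        stats = target
        if stats.n_g != params.n_g:
            params = replace(params, n_g=stats.n_g)
    if stats.E_n < 5:
        raise DegenerateTargetError(
            f"target mean order {stats.E_n:.2f} is below 5; the seed-and-grow "
            "scheme needs a larger target"
        )

    n_g = params.n_g
    s_n = max(stats.s_n, SIGMA_FLOOR)
    max_rej = params.max_rej
    if max_rej is None:
        max_rej = max(1, int(round(0.02 * stats.E_m)))

    if initial_graph is None:
        H = _seed_graph(stats, params.seed_fraction, rng)
    else:
        H = initial_graph.copy()
    C = count_all(H, n_g).astype(np.int64)
    next_node = max(H.nodes) + 1 if H.number_of_nodes() else 0
    reject_streak = 0
    accepted = 0
    step = 0
    # O(1) sampling registries; per-iteration work must stay local, so no
    # per-step rebuild of node or edge lists
    node_list, node_pos = _registry(H.nodes)
    edge_list, edge_pos = _registry(tuple(sorted(e)) for e in H.edges)
    if not stop_on_bounds and params.max_s is None:
        raise ValueError("stop_on_bounds=False requires a finite max_s")

    while params.max_s is None or step < params.max_s:
        step += 1
        P_H = _binned_fractions(H, stats)
        if stop_on_bounds and within_bounds(P_H, C, stats):
            return H
        if step % 1000 == 0:
            cb = cost(P_H, C, stats, params.w)
            logger.info(
                "step %d: n=%d m=%d cost_p=%.4f cost_c=%.4f",
                step, H.number_of_nodes(), H.number_of_edges(),
                cb.cost_p, cb.cost_c,
            )

        r = rng.random()
        n, m = H.number_of_nodes(), H.number_of_edges()
        move = None  # (kind, payload, delta)

        if step % params.node_step == 0:
            dn = (n - stats.E_n) / s_n
            if r > logistic_gate(dn):
                u = next_node
                edges = add_node_proposal(H, u, stats.cc_bar, rng)
                delta = delta_for_node(H, u, edges, True, n_g)
                move = ("add_node", (u, edges), delta)
            elif n > 2:
                u = node_list[rng.integers(len(node_list))]
                edges = [(u, x) for x in H._adj[u]]
                delta = delta_for_node(H, u, edges, False, n_g)
                move = ("del_node", (u, edges), delta)
        else:
            dm = edge_deviation(n, m, stats)
            if r > logistic_gate(dm):
                pair = _draw_nonedge(H, node_list, rng)
                if pair is not None:
                    delta = delta_for_edge(H, *pair, True, n_g)
                    move = ("add_edge", pair, delta)
            elif m > 0:
                pair = edge_list[rng.integers(len(edge_list))]
                delta = delta_for_edge(H, *pair, False, n_g)
                move = ("del_edge", pair, delta)

        if move is None:  # no feasible proposal this step
            reject_streak += 1
            continue

        kind, payload, delta = move
        C_T = C + delta
        P_T = _candidate_fractions(H, stats, kind, payload)
        cost_H = cost(P_H, C, stats, params.w)
        cost_T = cost(P_T, C_T, stats, params.w)

        if cost_T.total < cost_H.total or reject_streak >= max_rej:
            _apply(H, kind, payload)
            _apply_registry(kind, payload, node_list, node_pos, edge_list, edge_pos)
            C = C_T
            reject_streak = 0
            accepted += 1
            if kind in ("add_node",):
                next_node += 1
            if check_every and accepted % check_every == 0:
                assert np.array_equal(C, count_all(H, n_g)), (
                    "incremental counts diverged from full recount"
                )
        else:
            reject_streak += 1
    return H


def _registry(items) -> tuple[list, dict]:
    lst = list(items)
    return lst, {x: i for i, x in enumerate(lst)}


def _reg_add(lst: list, pos: dict, x) -> None:
    pos[x] = len(lst)
    lst.append(x)


def _reg_remove(lst: list, pos: dict, x) -> None:
    i = pos.pop(x)
    last = lst.pop()
    if last != x:
        lst[i] = last
        pos[last] = i


def _apply_registry(kind, payload, node_list, node_pos, edge_list, edge_pos):
    if kind == "add_edge":
        _reg_add(edge_list, edge_pos, tuple(sorted(payload)))
    elif kind == "del_edge":
        _reg_remove(edge_list, edge_pos, tuple(sorted(payload)))
    elif kind == "add_node":
        u, edges = payload
        _reg_add(node_list, node_pos, u)
        for e in edges:
            _reg_add(edge_list, edge_pos, tuple(sorted(e)))
    else:
        u, edges = payload
        _reg_remove(node_list, node_pos, u)
        for e in edges:
            _reg_remove(edge_list, edge_pos, tuple(sorted(e)))


def _draw_nonedge(
    H: nx.Graph, nodes: list, rng: np.random.Generator
) -> tuple | None:
    """Uniform non-adjacent node pair by rejection sampling; None when the
    graph is too small, error when it is essentially complete."""
    n = len(nodes)
    if n < 2 or H.number_of_edges() == n * (n - 1) // 2:
        return None
    for _ in range(MAX_NONEDGE_TRIES):
        i, j = rng.integers(n), rng.integers(n)
        if i != j and not H.has_edge(nodes[i], nodes[j]):
            return (nodes[i], nodes[j])
    raise RuntimeError("could not find a non-edge; graph is near-complete")


def _candidate_fractions(
    H: nx.Graph, stats: TargetStatistics, kind: str, payload
) -> np.ndarray:
    """Binned degree fractions of the candidate, without materializing it."""
    deg = dict(H.degree)
    if kind == "add_edge":
        u, v = payload
        deg[u] += 1
        deg[v] += 1
    elif kind == "del_edge":
        u, v = payload
        deg[u] -= 1
        deg[v] -= 1
    elif kind == "add_node":
        u, edges = payload
        deg[u] = len(edges)
        for _, x in edges:
            deg[x] += 1
    else:  # del_node
        u, edges = payload
        del deg[u]
        for _, x in edges:
            deg[x] -= 1
    n = len(deg)
    if n == 0:
        return np.zeros(stats.bins.n_bins)
    return binned_counts(deg.values(), stats.bins) / n


def _apply(H: nx.Graph, kind: str, payload) -> None:
    if kind == "add_edge":
        H.add_edge(*payload)
    elif kind == "del_edge":
        H.remove_edge(*payload)
    elif kind == "add_node":
        u, edges = payload
        H.add_node(u)
        H.add_edges_from(edges)
    else:
        u, _ = payload
        H.remove_node(u)
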