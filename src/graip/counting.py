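"""Graphlet counting: full enumeration, clustering coefficients and
incremental count updates for single edge/node modifications.

The full counter is ESU-style: every connected node set of size 3..n_g is
visited exactly once via exclusive-neighborhood extension and classified by
a bit-string table lookup.  The same anchored enumeration drives the
incremental updates: an edge edit can only touch graphlet instances whose
node set contains both endpoints (all within depth n_g - 2 of the edge),
a node edit only instances containing the node (depth n_g - 1), so deltas
are computed by enumerating those sets alone instead of recounting the
whole graph.
"""

from __future__ import annotations

from itertools import combinations
from typing import Hashable, Iterable, Iterator

import networkx as nx
import numpy as np

from .catalog import (
    ORDERS,
    bit_count_for_order,
    build_lookup_tables,
    n_types,
    pair_to_bit_position,
)

__all__ = [
    "count_all",
    "clustering_global",
    "clustering_local",
    "enumerate_connected_sets",
    "delta_for_edge",
    "delta_for_node",
]


def _classify_set(adj: dict, tables: dict, nodes: tuple) -> int:
    """Catalog index of the induced subgraph on ``nodes``; -1 if none."""
    bits = 0
    for a, b in combinations(range(1, len(nodes) + 1), 2):
        if nodes[b - 1] in adj[nodes[a - 1]]:
            bits |= 1 << pair_to_bit_position(a, b, len(nodes))
    return tables[len(nodes)][bits]


def enumerate_connected_sets(
    g: nx.Graph,
    anchor_nodes: Iterable[Hashable],
    max_order: int,
    min_order: int | None = None,
) -> Iterator[tuple]:
    """Yield every connected node set of size <= ``max_order`` that contains
    all anchors, each exactly once.

    The anchor set itself must induce a connected subgraph.  Extension uses
    the exclusive-neighborhood rule, so no deduplication bookkeeping beyond
    the recursion itself is needed.
    """
    anchors = tuple(anchor_nodes)
    if min_order is None:
        min_order = len(anchors)
    if len(anchors) > max_order:
        return
    adj = g._adj
    closed = set(anchors)
    ext: list = []
    for a in anchors:
        for w in adj[a]:
            if w not in closed:
                closed.add(w)
                ext.append(w)

    def extend(sub: list, ext: list, closed: set) -> Iterator[tuple]:
        if len(sub) >= min_order:
            yield tuple(sub)
        if len(sub) == max_order:
            return
        ext = list(ext)
        while ext:
            w = ext.pop()
            new_nbrs = [u for u in adj[w] if u not in closed]
            yield from extend(sub + [w], ext + new_nbrs, closed | set(new_nbrs))

    yield from extend(list(anchors), ext, closed)


def _all_connected_sets(g: nx.Graph, max_order: int) -> Iterator[tuple]:
    """All connected node sets of size 3..max_order, each exactly once.

    Classic ESU: each set is generated from its minimum-index node, and
    extension candidates are restricted to higher-index nodes.
    """
    index = {v: i for i, v in enumerate(g.nodes)}
    adj = g._adj

    for root in g.nodes:
        ri = index[root]
        closed = {root}
        ext = []
        for w in adj[root]:
            if index[w] > ri:
                closed.add(w)
                ext.append(w)

        def extend(sub: list, ext: list, closed: set) -> Iterator[tuple]:
            if len(sub) >= 3:
                yield tuple(sub)
            if len(sub) == max_order:
                return
            ext = list(ext)
            while ext:
                w = ext.pop()
                new_nbrs = [u for u in adj[w] if index[u] > ri and u not in closed]
                yield from extend(sub + [w], ext + new_nbrs, closed | set(new_nbrs))

        yield from extend([root], ext, closed)


def count_all(g: nx.Graph, n_g: int) -> np.ndarray:
    """Exact induced graphlet counts of all types of order 3..``n_g``.

    Returns the count vector in catalog order (length 2, 8 or 29).  Each
    connected node set is counted once; two instances are distinct if they
    differ in at least one node.
    """
    if n_g not in ORDERS:
        raise ValueError(f"n_g must be in {ORDERS}, got {n_g}")
    tables = build_lookup_tables()
    adj = g._adj
    counts = np.zeros(n_types(n_g), dtype=np.int64)
    for nodes in _all_connected_sets(g, n_g):
        counts[_classify_set(adj, tables, nodes)] += 1
    return counts


def clustering_global(counts: np.ndarray) -> float:
    """Global clustering coefficient 3T / (W + 3T) from order-3 counts.

    T is the triangle count (M2), W the count of open connected triplets
    (M1).  Defined as 0 when the graph has no connected triplet at all.
    """
    w, t = float(counts[0]), float(counts[1])
    denom = w + 3.0 * t
    return 0.0 if denom == 0.0 else 3.0 * t / denom


def clustering_local(g: nx.Graph, v: Hashable) -> float:
    """Local clustering coefficient 2 t_v / (k_v (k_v - 1)); 0 for k_v < 2."""
    if v not in g:
        raise KeyError(f"unknown node {v!r}")
    nbrs = list(g._adj[v])
    k = len(nbrs)
    if k < 2:
        return 0.0
    t = sum(1 for a, b in combinations(nbrs, 2) if g.has_edge(a, b))
    return 2.0 * t / (k * (k - 1))


def delta_for_edge(
    g: nx.Graph, u: Hashable, v: Hashable, adding: bool, n_g: int
) -> np.ndarray:
    """Signed per-type count change caused by adding or removing edge (u, v).

    Enumeration always runs on the graph *with* the edge present (a set may
    be connected only through it); each set's bit-string is classified with
    the (u, v) bit set and cleared, and the difference is accumulated.
    Satisfies ``count_all(after) == count_all(before) + delta``.
    """
    has = g.has_edge(u, v)
    if adding and has:
        raise ValueError(f"edge ({u!r}, {v!r}) already present")
    if not adding and not has:
        raise ValueError(f"edge ({u!r}, {v!r}) not present")
    if u == v:
        raise ValueError("self-loop")
    tables = build_lookup_tables()
    delta = np.zeros(n_types(n_g), dtype=np.int64)
    temporarily_added = adding
    if temporarily_added:
        g.add_edge(u, v)
    try:
        adj = g._adj
        for nodes in enumerate_connected_sets(g, (u, v), n_g, min_order=3):
            order = len(nodes)
            iu, iv = nodes.index(u) + 1, nodes.index(v) + 1
            if iu > iv:
                iu, iv = iv, iu
            uv_mask = 1 << pair_to_bit_position(iu, iv, order)
            bits = 0
            for a, b in combinations(range(1, order + 1), 2):
                if nodes[b - 1] in adj[nodes[a - 1]]:
                    bits |= 1 << pair_to_bit_position(a, b, order)
            with_idx = tables[order][bits]
            without_idx = tables[order][bits ^ uv_mask]
            if with_idx >= 0:
                delta[with_idx] += 1
            if without_idx >= 0:
                delta[without_idx] -= 1
    finally:
        if temporarily_added:
            g.remove_edge(u, v)
    return delta if adding else -delta


def delta_for_node(
    g: nx.Graph,
    u: Hashable,
    incident_edges: Iterable[tuple],
    adding: bool,
    n_g: int,
) -> np.ndarray:
    """Signed per-type count change caused by inserting or deleting node
    ``u`` together with ``incident_edges``.

    A node edit can only create (insert) or destroy (delete) instances, all
    of which contain ``u``, so the delta is +/- the classification of every
    connected set through ``u`` in the graph with the node present.
    """
    neighbors = set()
    for e in incident_edges:
        a, b = e
        if a == u:
            neighbors.add(b)
        elif b == u:
            neighbors.add(a)
        else:
            raise ValueError(f"edge {e!r} not incident to {u!r}")
    if adding:
        if u in g:
            raise ValueError(f"node {u!r} already present")
        missing = [w for w in neighbors if w not in g]
        if missing:
            raise ValueError(f"neighbor nodes not in graph: {missing!r}")
    else:
        if u not in g:
            raise ValueError(f"node {u!r} not present")
        if neighbors != set(g._adj[u]):
            raise ValueError("incident_edges do not match the node's edges")

    tables = build_lookup_tables()
    delta = np.zeros(n_types(n_g), dtype=np.int64)
    if adding:
        g.add_node(u)
        g.add_edges_from((u, w) for w in neighbors)
    try:
        adj = g._adj
        for nodes in enumerate_connected_sets(g, (u,), n_g, min_order=3):
            idx = _classify_set(adj, tables, nodes)
            if idx >= 0:
                delta[idx] += 1
    finally:
        if adding:
            g.remove_node(u)
    return delta if adding else -delta
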