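"""Catalog of the 29 undirected graphlets of orders 3-5.

A graphlet is a small connected induced subgraph.  There are 2 connected
non-isomorphic graphs on 3 nodes, 6 on 4 nodes and 21 on 5 nodes; the
catalog labels them M1..M29.  Labeled subgraphs are encoded as bit-strings:
for an order-n_S subgraph with an arbitrary node ordering, the pair
(v_i, v_j) with 1 <= i < j <= n_S maps to bit position

    (j - 1)(j - 2) / 2 + (i - 1)

(least significant bit at position zero), so orders 3/4/5 use 3/6/10 bits.
All 2^3 + 2^6 + 2^10 bit-strings are classified once, up front, by brute
force canonicalization over node permutations; classifying a subgraph at
run time is then a single table lookup.

Catalog numbering is fixed by sorting types by (order, edge count,
descending degree sequence), which anchors M1 = 3-path, M2 = triangle,
M3 = 4-star, M8 = 4-clique and M29 = 5-clique.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations
from typing import Callable, Hashable, Sequence

__all__ = [
    "GraphletType",
    "ORDERS",
    "pair_to_bit_position",
    "bit_count_for_order",
    "graphlet_types",
    "n_types",
    "build_lookup_tables",
    "classify_subgraph",
    "classify_index",
]

ORDERS = (3, 4, 5)


@dataclass(frozen=True)
class GraphletType:
    """One of the 29 graphlet isomorphism classes of orders 3-5."""

    id: str              # "M1".."M29"
    index: int           # 0-based position in the catalog order
    order: int           # number of nodes (3, 4 or 5)
    edge_count: int
    canonical_bitstrings: frozenset[int] = field(repr=False)

    def __str__(self) -> str:
        return self.id


def pair_to_bit_position(i: int, j: int, order: int) -> int:
    """Bit position of node pair (i, j), 1-based with i < j <= order."""
    if not (1 <= i < j <= order):
        raise ValueError(f"need 1 <= i < j <= order, got i={i}, j={j}, order={order}")
    return (j - 1) * (j - 2) // 2 + (i - 1)


def bit_count_for_order(order: int) -> int:
    return order * (order - 1) // 2


def _is_connected(bits: int, order: int) -> bool:
    """Connectivity of the labeled graph encoded by ``bits`` (union-find)."""
    parent = list(range(order))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in combinations(range(1, order + 1), 2):
        if bits >> pair_to_bit_position(i, j, order) & 1:
            ri, rj = find(i - 1), find(j - 1)
            if ri != rj:
                parent[ri] = rj
    root = find(0)
    return all(find(x) == root for x in range(order))


def _bit_permutations(order: int) -> list[list[int]]:
    """For each node permutation, the induced map old bit pos -> new bit pos."""
    maps = []
    for perm in permutations(range(order)):
        bitmap = [0] * bit_count_for_order(order)
        for i, j in combinations(range(1, order + 1), 2):
            old = pair_to_bit_position(i, j, order)
            a, b = perm[i - 1] + 1, perm[j - 1] + 1
            if a > b:
                a, b = b, a
            bitmap[old] = pair_to_bit_position(a, b, order)
        maps.append(bitmap)
    return maps


def _degree_sequence(bits: int, order: int) -> tuple[int, ...]:
    deg = [0] * order
    for i, j in combinations(range(1, order + 1), 2):
        if bits >> pair_to_bit_position(i, j, order) & 1:
            deg[i - 1] += 1
            deg[j - 1] += 1
    return tuple(sorted(deg, reverse=True))


@lru_cache(maxsize=1)
def _catalog() -> tuple[tuple[GraphletType, ...], dict[int, list[int]]]:
    """Build the full type list and per-order lookup tables (bits -> index).

    Rebuilt on first use per process; takes well under a second.
    """
    per_order_classes: dict[int, dict[int, set[int]]] = {}
    for order in ORDERS:
        nbits = bit_count_for_order(order)
        bitmaps = _bit_permutations(order)
        classes: dict[int, set[int]] = {}
        for bits in range(1 << nbits):
            if not _is_connected(bits, order):
                continue
            canon = bits
            members = set()
            for bitmap in bitmaps:
                img = 0
                b = bits
                while b:
                    low = b & -b
                    img |= 1 << bitmap[low.bit_length() - 1]
                    b ^= low
                members.add(img)
                if img < canon:
                    canon = img
            if canon not in classes:
                classes[canon] = members
        per_order_classes[order] = classes

    # Deterministic catalog numbering across orders.
    keyed = []
    for order in ORDERS:
        for canon, members in per_order_classes[order].items():
            ec = bin(canon).count("1")
            degs = _degree_sequence(canon, order)
            keyed.append(((order, ec, tuple(-d for d in degs), canon), order, ec, members))
    keyed.sort(key=lambda t: t[0])

    types = []
    tables = {order: [-1] * (1 << bit_count_for_order(order)) for order in ORDERS}
    for idx, (_, order, ec, members) in enumerate(keyed):
        types.append(
            GraphletType(
                id=f"M{idx + 1}",
                index=idx,
                order=order,
                edge_count=ec,
                canonical_bitstrings=frozenset(members),
            )
        )
        for bits in members:
            tables[order][bits] = idx
    return tuple(types), tables


def graphlet_types(n_g: int = 5) -> tuple[GraphletType, ...]:
    """All graphlet types of order <= ``n_g``, in catalog order."""
    if n_g not in ORDERS:
        raise ValueError(f"n_g must be one of {ORDERS}, got {n_g}")
    return tuple(t for t in _catalog()[0] if t.order <= n_g)


def n_types(n_g: int) -> int:
    """Length of the count vector for max order ``n_g`` (2, 8 or 29)."""
    return {3: 2, 4: 8, 5: 29}[n_g]


def build_lookup_tables() -> dict[int, list[int]]:
    """Per-order tables mapping a bit-string to a catalog index (or -1)."""
    return _catalog()[1]


def classify_index(
    nodes: Sequence[Hashable],
    adjacency_test: Callable[[Hashable, Hashable], bool],
) -> int:
    """Catalog index of the induced subgraph on ``nodes``; -1 if disconnected."""
    order = len(nodes)
    bits = 0
    for i, j in combinations(range(1, order + 1), 2):
        if adjacency_test(nodes[i - 1], nodes[j - 1]):
            bits |= 1 << pair_to_bit_position(i, j, order)
    return _catalog()[1][order][bits]


def classify_subgraph(
    nodes: Sequence[Hashable],
    adjacency_test: Callable[[Hashable, Hashable], bool],
) -> GraphletType | None:
    """Graphlet type of the induced subgraph on the node tuple.

    The result is independent of the ordering of ``nodes`` because the
    lookup tables are closed under isomorphism.  Returns ``None`` for a
    disconnected induced subgraph.
    """
    order = len(nodes)
    if order not in ORDERS:
        raise ValueError(f"subgraph order must be in {ORDERS}, got {order}")
    if len(set(nodes)) != order:
        raise ValueError("duplicate nodes in subgraph tuple")
    idx = classify_index(nodes, adjacency_test)
    return None if idx < 0 else _catalog()[0][idx]
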