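"""Possible-world semantics for probabilistic graphs.

An uncertain graph represents a distribution over the 2^|E| deterministic
graphs obtained by independently keeping each edge e with probability P(e).
This module samples such *possible worlds*, evaluates their probability in
closed form, and provides the exact per-node degree moments

    E[k_v]   = sum over incident edges of P(e)
    Var[k_v] = sum over incident edges of P(e) (1 - P(e))

which follow from the degree being a sum of independent Bernoullis.
"""

from __future__ import annotations

import math
from typing import Hashable, Iterable

import networkx as nx
import numpy as np

from .graphs import UncertainGraph, _edge_key

__all__ = [
    "sample_world",
    "world_probability",
    "node_degree_moments",
    "largest_connected_component",
]


def sample_world(g: UncertainGraph, rng: np.random.Generator) -> nx.Graph:
    """Draw one possible world by independent per-edge Bernoulli trials.

    Edge draws are consumed in canonical sorted-edge order so that a given
    RNG state always yields the same world regardless of edge insertion
    order.  The node set is carried over in full.
    """
    world = nx.Graph()
    world.add_nodes_from(g.nodes)
    edges = g.sorted_edges()
    draws = rng.random(len(edges))
    for (u, v), r in zip(edges, draws):
        if r < g.probability(u, v):
            world.add_edge(u, v)
    return world


def world_probability(g: UncertainGraph, world_edges: Iterable[tuple]) -> float:
    """Existential probability of the world with exactly ``world_edges``:
    the product of P(e) over included edges times (1 - P(e)) over the rest.
    """
    included = {frozenset(e) for e in world_edges}
    backbone = {frozenset(e) for e in g.edges}
    foreign = included - backbone
    if foreign:
        raise ValueError(f"edges not in backbone: {sorted(map(tuple, foreign))}")
    prob = 1.0
    for u, v in g.edges:
        p = g.probability(u, v)
        prob *= p if frozenset((u, v)) in included else (1.0 - p)
    return prob


def node_degree_moments(g: UncertainGraph, v: Hashable) -> tuple[float, float]:
    """Exact mean and variance of the degree of ``v`` across possible worlds."""
    if v not in g.nodes:
        raise KeyError(f"unknown node {v!r}")
    probs = [g.probability(v, w) for w in g._g.neighbors(v)]
    mean = float(sum(probs))
    var = float(sum(p * (1.0 - p) for p in probs))
    return mean, var


def largest_connected_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest component (copy).

    Size ties are broken in favor of the component containing the smallest
    node label (string comparison), so extraction is deterministic.  An
    empty graph maps to an empty graph.
    """
    if g.number_of_nodes() == 0:
        return nx.Graph()
    components = [set(c) for c in nx.connected_components(g)]
    best = max(components, key=lambda c: (len(c), _neg_min_label(c)))
    return g.subgraph(best).copy()


def _neg_min_label(component: set) -> tuple:
    # Larger is better in the max() key, so invert the string ordering of
    # the smallest label via a negated character tuple.
    label = min(str(v) for v in component)
    return tuple(-ord(ch) for ch in label)
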