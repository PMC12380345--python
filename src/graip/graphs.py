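"""Probabilistic-graph data model, edge-list I/O and synthetic fixtures.

An *uncertain* (probabilistic) graph is an undirected simple graph whose
edges carry independent existence probabilities P(e) in (0, 1].  Dropping
the probabilities yields the *backbone* graph.  PPI networks exported from
interaction databases with confidence scores reduce to exactly this model,
serialized as a whitespace-separated edge list ``node_u node_v probability``.

Deterministic graphs are plain :class:`networkx.Graph` instances throughout
the package.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Iterator, Hashable

import networkx as nx
import numpy as np

__all__ = [
    "UncertainGraph",
    "ValidationError",
    "read_probabilistic_edgelist",
    "read_edgelist",
    "write_edgelist",
    "make_uncertain_er",
    "make_uncertain_ba",
    "make_uncertain_star",
]


class ValidationError(ValueError):
    """Raised when an edge list or edge probability violates the model."""


def _edge_key(u: Hashable, v: Hashable) -> tuple:
    """Orientation-free edge key, ordered by string form for mixed types."""
    return (u, v) if str(u) <= str(v) else (v, u)


class UncertainGraph:
    """Undirected simple graph with a per-edge existence probability.

    Parameters
    ----------
    graph:
        Optional backbone :class:`networkx.Graph` whose edges carry a
        ``"p"`` attribute in (0, 1].  Validated on construction.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self._g = nx.Graph()
        if graph is not None:
            for n in graph.nodes:
                self._g.add_node(n)
            for u, v, data in graph.edges(data=True):
                self.add_edge(u, v, data.get("p", 1.0))

    # -- construction -----------------------------------------------------

    def add_node(self, v: Hashable) -> None:
        self._g.add_node(v)

    def add_edge(self, u: Hashable, v: Hashable, p: float) -> None:
        if u == v:
            raise ValidationError(f"self-loop on node {u!r}")
        if not (0.0 < p <= 1.0):
            raise ValidationError(
                f"edge ({u!r}, {v!r}) has probability {p} outside (0, 1]"
            )
        if self._g.has_edge(u, v):
            raise ValidationError(f"duplicate edge ({u!r}, {v!r})")
        self._g.add_edge(u, v, p=float(p))

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self):
        return self._g.nodes

    @property
    def edges(self):
        return self._g.edges

    def probability(self, u: Hashable, v: Hashable) -> float:
        return self._g.edges[u, v]["p"]

    def number_of_nodes(self) -> int:
        return self._g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def backbone(self) -> nx.Graph:
        """Deterministic graph obtained by keeping all edges."""
        g = nx.Graph()
        g.add_nodes_from(self._g.nodes)
        g.add_edges_from(self._g.edges)
        return g

    def sorted_edges(self) -> list[tuple]:
        """Edges in a canonical order (used to fix the RNG draw order)."""
        return sorted(
            (_edge_key(u, v) for u, v in self._g.edges),
            key=lambda e: (str(e[0]), str(e[1])),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, UncertainGraph):
            return NotImplemented
        if set(self.nodes) != set(other.nodes):
            return False
        if set(map(frozenset, self.edges)) != set(map(frozenset, other.edges)):
            return False
        return all(
            math.isclose(self.probability(u, v), other.probability(u, v))
            for u, v in self.edges
        )

    def __repr__(self) -> str:
        return (
            f"UncertainGraph(n={self.number_of_nodes()}, "
            f"m={self.number_of_edges()})"
        )


# -- I/O ------------------------------------------------------------------


def _tokenized_lines(path: Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split()


def read_probabilistic_edgelist(path: str | Path) -> UncertainGraph:
    """Parse a 3-column ``u v p`` edge list into an :class:`UncertainGraph`.

    Lines starting with ``#`` and blank lines are ignored; node identifiers
    are opaque strings.  Self-loops, duplicate edges and probabilities
    outside (0, 1] raise :class:`ValidationError` naming the line.
    """
    g = UncertainGraph()
    for lineno, tokens in _tokenized_lines(Path(path)):
        if len(tokens) != 3:
            raise ValidationError(
                f"{path}:{lineno}: expected 'u v p', got {len(tokens)} tokens"
            )
        u, v, ptok = tokens
        try:
            p = float(ptok)
        except ValueError as exc:
            raise ValidationError(
                f"{path}:{lineno}: cannot parse probability {ptok!r}"
            ) from exc
        try:
            g.add_edge(u, v, p)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return g


def read_edgelist(path: str | Path) -> nx.Graph:
    """Parse a 2-column deterministic edge list."""
    g = nx.Graph()
    for lineno, tokens in _tokenized_lines(Path(path)):
        if len(tokens) != 2:
            raise ValidationError(
                f"{path}:{lineno}: expected 'u v', got {len(tokens)} tokens"
            )
        u, v = tokens
        if u == v:
            raise ValidationError(f"{path}:{lineno}: self-loop on {u!r}")
        g.add_edge(u, v)
    return g


def write_edgelist(graph: nx.Graph | UncertainGraph, path: str | Path) -> None:
    """Write a graph as a whitespace-separated edge list.

    Deterministic graphs produce two columns, uncertain graphs three
    (the probability column).  Round-trips through the readers above.
    """
    path = Path(path)
    with open(path, "w") as fh:
        if isinstance(graph, UncertainGraph):
            for u, v in graph.sorted_edges():
                fh.write(f"{u}\t{v}\t{graph.probability(u, v):.10g}\n")
        else:
            edges = sorted(
                (_edge_key(u, v) for u, v in graph.edges),
                key=lambda e: (str(e[0]), str(e[1])),
            )
            for u, v in edges:
                fh.write(f"{u}\t{v}\n")


# -- synthetic fixtures ---------------------------------------------------


def _attach_probabilities(backbone: nx.Graph, rng: np.random.Generator) -> UncertainGraph:
    g = UncertainGraph()
    for n in backbone.nodes:
        g.add_node(n)
    # 1 - U[0,1) lies in (0,1], matching the P: E -> (0,1] domain
    for u, v in sorted(backbone.edges, key=lambda e: (str(e[0]), str(e[1]))):
        g.add_edge(u, v, 1.0 - rng.random())
    return g


def make_uncertain_er(n: int, mean_degree: float, rng_seed: int) -> UncertainGraph:
    """Uncertain Erdős–Rényi fixture with uniform-(0,1] edge probabilities.

    The backbone is a G(n, m) draw with ``m = round(n * mean_degree / 2)``
    so the average backbone degree is hit exactly.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(rng_seed)
    m = int(round(n * mean_degree / 2.0))
    backbone = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
    return _attach_probabilities(backbone, rng)


def make_uncertain_ba(n: int, mean_degree: float, rng_seed: int) -> UncertainGraph:
    """Uncertain Barabási–Albert fixture with uniform-(0,1] probabilities.

    A preferential-attachment backbone is drawn, then edges are randomly
    added or removed to reach exactly ``round(n * mean_degree / 2)`` edges,
    preserving the heavy-tailed degree sequence while pinning the size.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(rng_seed)
    m_target = int(round(n * mean_degree / 2.0))
    attach = max(1, int(mean_degree // 2))
    attach = min(attach, n - 1)
    backbone = nx.barabasi_albert_graph(n, attach, seed=int(rng.integers(2**31)))
    _adjust_edge_count(backbone, m_target, rng)
    return _attach_probabilities(backbone, rng)


def _adjust_edge_count(g: nx.Graph, m_target: int, rng: np.random.Generator) -> None:
    """Add or remove uniformly random (non-)edges until ``m == m_target``."""
    nodes = list(g.nodes)
    n = len(nodes)
    max_m = n * (n - 1) // 2
    m_target = min(m_target, max_m)
    while g.number_of_edges() > m_target:
        edges = list(g.edges)
        u, v = edges[rng.integers(len(edges))]
        g.remove_edge(u, v)
    while g.number_of_edges() < m_target:
        u, v = rng.choice(n, size=2, replace=False)
        u, v = nodes[u], nodes[v]
        if not g.has_edge(u, v):
            g.add_edge(u, v)


def make_uncertain_star(n: int, p: float) -> UncertainGraph:
    """Star on ``n`` nodes (one hub, ``n - 1`` leaves) with uniform edge
    probability ``p``; the canonical sharp-degree-peak fixture."""
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not (0.0 < p <= 1.0):
        raise ValidationError(f"probability {p} outside (0, 1]")
    g = UncertainGraph()
    for leaf in range(1, n):
        g.add_edge(0, leaf, p)
    return g
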