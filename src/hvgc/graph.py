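"""Undirected simple graphs: edge-list I/O, BFS distances, whole-network descriptors.

The graph container is deliberately small: node labels are opaque strings (or
ints) kept in first-appearance order, adjacency is symmetric, and self-loops /
parallel edges are rejected at construction.  Deterministic iteration order is
what makes downstream tie-breaking (top-k sets, ranking exports) reproducible.
"""

from __future__ import annotations

import json
import logging
import math
from collections import deque
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import IO, Hashable, Iterable, Iterator

import numpy as np

logger = logging.getLogger(__name__)

Label = Hashable

__all__ = [
    "Graph",
    "NetworkStats",
    "EdgeListParseError",
    "read_edge_list",
    "write_edge_list",
    "shortest_distances",
    "distance_matrix",
    "diameter",
    "network_stats",
    "degree_moments",
]


class EdgeListParseError(ValueError):
    """Raised when an edge-list line cannot be interpreted."""


class Graph:
    """Undirected, unweighted simple graph with stable node order.

    Adjacency is stored as ``dict[label, dict[label, None]]`` so that both
    membership tests and insertion-ordered iteration are O(1)/deterministic.
    """

    __slots__ = ("_adj", "_m")

    def __init__(self, edges: Iterable[tuple[Label, Label]] | None = None) -> None:
        self._adj: dict[Label, dict[Label, None]] = {}
        self._m = 0
        if edges is not None:
            for u, v in edges:
                self.add_edge(u, v)

    # -- construction -------------------------------------------------
    def add_node(self, u: Label) -> None:
        if u not in self._adj:
            self._adj[u] = {}

    def add_edge(self, u: Label, v: Label) -> None:
        if u == v:
            raise ValueError(f"self-loop on node {u!r} is not allowed")
        self.add_node(u)
        self.add_node(v)
        if v not in self._adj[u]:
            self._adj[u][v] = None
            self._adj[v][u] = None
            self._m += 1

    # -- queries ------------------------------------------------------
    @property
    def nodes(self) -> list[Label]:
        return list(self._adj)

    @property
    def number_of_nodes(self) -> int:
        return len(self._adj)

    @property
    def number_of_edges(self) -> int:
        return self._m

    def __contains__(self, u: Label) -> bool:
        return u in self._adj

    def __len__(self) -> int:
        return len(self._adj)

    def __iter__(self) -> Iterator[Label]:
        return iter(self._adj)

    def degree(self, u: Label) -> int:
        return len(self._adj[u])

    def degrees(self) -> dict[Label, int]:
        return {u: len(nbrs) for u, nbrs in self._adj.items()}

    def neighbors(self, u: Label) -> list[Label]:
        return list(self._adj[u])

    def has_edge(self, u: Label, v: Label) -> bool:
        return u in self._adj and v in self._adj[u]

    def edges(self) -> Iterator[tuple[Label, Label]]:
        """Each edge once, ordered by the first endpoint's node order."""
        index = {u: i for i, u in enumerate(self._adj)}
        for u, nbrs in self._adj.items():
            for v in nbrs:
                if index[u] < index[v]:
                    yield u, v

    def relabel(self, mapping: dict[Label, Label]) -> "Graph":
        g = Graph()
        for u in self._adj:
            g.add_node(mapping[u])
        for u, v in self.edges():
            g.add_edge(mapping[u], mapping[v])
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return list(self._adj) == list(other._adj) and {
            u: set(n) for u, n in self._adj.items()
        } == {u: set(n) for u, n in other._adj.items()}

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Graph(N={self.number_of_nodes}, M={self.number_of_edges})"


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------

def _detect_delimiter(line: str) -> str | None:
    return "," if "," in line else None  # None => any whitespace


def read_edge_list(
    source: str | Path | IO[str],
    delimiter: str = "auto",
) -> Graph:
    """Parse a plain-text edge list into a :class:`Graph`.

    One edge per line, two labels separated by whitespace or commas (extra
    tokens ignored); ``#`` comments and blank lines are skipped.  Duplicate
    edges are merged; self-loops are dropped (count logged).  Node order is
    first-appearance order, which fixes every downstream tie-break.
    """
    close_after = False
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.exists():
            stream: IO[str] = path.open()
            close_after = True
        else:
            stream = StringIO(str(source))
    else:
        stream = source

    g = Graph()
    sep: str | None = None if delimiter in ("auto",) else delimiter
    sep_resolved = delimiter != "auto"
    self_loops = 0
    saw_data = False
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not sep_resolved:
            sep = _detect_delimiter(line)
            sep_resolved = True
        tokens = [t for t in line.split(sep) if t]
        if len(tokens) < 2:
            raise EdgeListParseError(
                f"line {lineno}: expected at least two node labels, got {line!r}"
            )
        saw_data = True
        u, v = tokens[0], tokens[1]
        if u == v:
            self_loops += 1
            g.add_node(u)
            continue
        g.add_edge(u, v)
    if close_after:
        stream.close()
    if not saw_data:
        raise EdgeListParseError("empty edge list: no data lines found")
    if self_loops:
        logger.info("dropped %d self-loop(s) while parsing edge list", self_loops)
    return g


def write_edge_list(g: Graph, stream: IO[str], delimiter: str = "\t") -> None:
    for u, v in g.edges():
        stream.write(f"{u}{delimiter}{v}\n")


# ---------------------------------------------------------------------------
# Shortest paths
# ---------------------------------------------------------------------------

def shortest_distances(
    g: Graph,
    source: Label,
    radius: int | None = None,
) -> dict[Label, int]:
    """BFS hop counts from ``source``; nodes beyond ``radius`` or unreachable
    are absent.  The source itself is included with distance 0 (gravity sums
    skip it explicitly)."""
    if source not in g:
        raise KeyError(f"unknown source node {source!r}")
    dist: dict[Label, int] = {source: 0}
    frontier = deque([source])
    while frontier:
        u = frontier.popleft()
        du = dist[u]
        if radius is not None and du >= radius:
            continue
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = du + 1
                frontier.append(v)
    return dist


def distance_matrix(g: Graph, radius: int | None = None) -> dict[Label, dict[Label, int]]:
    """All-sources BFS; a dict-of-dicts to keep labels opaque."""
    return {u: shortest_distances(g, u, radius=radius) for u in g}


def diameter(g: Graph) -> int:
    """Largest finite shortest-path distance (0 for edgeless graphs)."""
    best = 0
    for u in g:
        d = shortest_distances(g, u)
        if d:
            best = max(best, max(d.values()))
    return best


# ---------------------------------------------------------------------------
# Whole-network descriptors
# ---------------------------------------------------------------------------

_STATS_COLUMNS = ("N", "M", "k_mean", "d_mean", "C", "r", "H", "beta_c")


@dataclass(frozen=True)
class NetworkStats:
    """Descriptor bundle: size, degree moments, distances, clustering,
    assortativity, heterogeneity and the SIR epidemic threshold."""

    n: int
    m: int
    k_mean: float
    d_mean: float
    clustering: float
    assortativity: float
    heterogeneity: float
    beta_c: float

    def as_dict(self) -> dict[str, float]:
        return {
            "N": self.n,
            "M": self.m,
            "k_mean": self.k_mean,
            "d_mean": self.d_mean,
            "C": self.clustering,
            "r": self.assortativity,
            "H": self.heterogeneity,
            "beta_c": self.beta_c,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict())

    def to_tsv(self) -> str:
        d = self.as_dict()
        header = "\t".join(_STATS_COLUMNS)
        row = "\t".join(
            str(d[c]) if c in ("N", "M") else format(d[c], ".6g") for c in _STATS_COLUMNS
        )
        return f"{header}\n{row}\n"


def degree_moments(g: Graph) -> tuple[float, float]:
    """(⟨k⟩, ⟨k²⟩) of the degree distribution."""
    degs = np.array([g.degree(u) for u in g], dtype=float)
    return float(degs.mean()), float((degs**2).mean())


def mean_distance(g: Graph) -> float:
    """Average shortest-path distance over reachable unordered pairs.

    Disconnected pairs are excluded (count logged) so the descriptor stays
    defined on graphs with several components.
    """
    n = g.number_of_nodes
    total = 0
    reachable_ordered = 0
    for u in g:
        d = shortest_distances(g, u)
        total += sum(d.values())
        reachable_ordered += len(d) - 1
    if reachable_ordered == 0:
        raise ValueError("mean distance undefined: no connected pair of nodes")
    excluded = n * (n - 1) - reachable_ordered
    if excluded:
        logger.info("mean_distance: excluded %d unreachable ordered pairs", excluded)
    return total / reachable_ordered


def mean_clustering(g: Graph) -> float:
    """Mean local clustering coefficient; degree<2 nodes contribute 0."""
    from .indices import local_clustering  # local import avoids a cycle

    c = local_clustering(g)
    return float(np.mean(list(c.scores.values())))


def assortativity(g: Graph) -> float:
    """Pearson correlation of degrees across edge endpoints (both directions).

    Undefined (NaN) for degree-regular graphs where the variance vanishes.
    """
    xs: list[int] = []
    ys: list[int] = []
    for u, v in g.edges():
        ku, kv = g.degree(u), g.degree(v)
        xs.extend((ku, kv))
        ys.extend((kv, ku))
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    sx = x.std()
    if sx == 0.0:
        return math.nan
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * y.std()))


def network_stats(g: Graph) -> NetworkStats:
    """Compute the standard descriptor bundle for an undirected graph."""
    n, m = g.number_of_nodes, g.number_of_edges
    if n < 2 or m < 1:
        raise ValueError("network_stats requires N >= 2 and M >= 1")
    k1, k2 = degree_moments(g)
    if k2 <= k1:
        raise ValueError("epidemic threshold undefined: <k^2> <= <k>")
    return NetworkStats(
        n=n,
        m=m,
        k_mean=k1,
        d_mean=mean_distance(g),
        clustering=mean_clustering(g),
        assortativity=assortativity(g),
        heterogeneity=k2 / (k1 * k1),
        beta_c=k1 / (k2 - k1),
    )
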