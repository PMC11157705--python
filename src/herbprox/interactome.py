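"""The protein interactome graph and unweighted shortest-path distances.

The interactome is an undirected simple graph whose nodes are genes/proteins
and whose edges are protein-protein interactions. All proximity measures are
evaluated on its largest connected component (LCC), which guarantees every
pairwise distance is finite. :class:`DistanceOracle` serves exact breadth-first
shortest-path lengths with per-source memoisation, so repeated queries from the
same gene (the common access pattern when scoring every herb against one
disease) cost a single traversal.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MissingNodeError",
    "DegreeSummary",
    "load_edge_list",
    "build_graph",
    "largest_connected_component",
    "DistanceOracle",
    "degree_summary",
]


class MissingNodeError(KeyError):
    """A queried gene is not a node of the interactome."""


def load_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read an edge list TSV with header ``gene_a<TAB>gene_b``.

    A third column (e.g. an interaction type) is ignored; lines beginning with
    ``#`` are skipped.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"edge list {path} is empty") from None
    missing = {"gene_a", "gene_b"} - set(df.columns)
    if missing:
        raise ValueError(f"edge list {path} lacks required columns: {sorted(missing)}")
    return list(zip(df["gene_a"], df["gene_b"]))


def build_graph(edge_list: Iterable[tuple[str, str]]) -> nx.Graph:
    """Build an undirected simple graph from raw gene pairs.

    Self-loops are dropped; duplicate and reversed-duplicate pairs collapse to
    one undirected edge. Direction in the source, if any, is discarded —
    distance-based proximity never uses it.
    """
    g = nx.Graph()
    n_raw = 0
    for a, b in edge_list:
        n_raw += 1
        if not a or not b:
            raise ValueError(f"edge endpoints must be non-empty strings: ({a!r}, {b!r})")
        if a == b:
            continue
        g.add_edge(a, b)
    if n_raw == 0:
        raise ValueError("empty edge list")
    logger.info(
        "built interactome: %d raw pairs -> %d nodes, %d edges",
        n_raw,
        g.number_of_nodes(),
        g.number_of_edges(),
    )
    return g


def largest_connected_component(g: nx.Graph) -> nx.Graph:
    """Return the maximum-cardinality connected component as a new graph.

    Size ties are broken deterministically in favour of the component holding
    the lexicographically smallest node identifier.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot take the LCC of an empty graph")
    best = max(nx.connected_components(g), key=lambda c: (len(c), _neg_min(c)))
    lcc = g.subgraph(best).copy()
    if lcc.number_of_nodes() < g.number_of_nodes():
        logger.info(
            "LCC: kept %d of %d nodes, %d of %d edges",
            lcc.number_of_nodes(),
            g.number_of_nodes(),
            lcc.number_of_edges(),
            g.number_of_edges(),
        )
    return lcc


class _neg_min:
    """Order helper: prefers the component whose smallest node id sorts first."""

    def __init__(self, component):
        self.value = min(component)

    def __lt__(self, other: "_neg_min") -> bool:
        return self.value > other.value  # larger min id loses the tie


class DistanceOracle:
    """Exact unweighted shortest-path lengths with memoised BFS.

    One breadth-first traversal per distinct source gene is cached; the graph
    is expected (but not required) to be connected, as after LCC extraction.
    """

    def __init__(self, graph: nx.Graph):
        self.graph = graph
        self._cache: dict[str, Mapping[str, int]] = {}

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    def distances_from(self, source: str) -> Mapping[str, int]:
        """All distances from ``source`` as a node→length mapping."""
        if source not in self.graph:
            raise MissingNodeError(source)
        dists = self._cache.get(source)
        if dists is None:
            dists = nx.single_source_shortest_path_length(self.graph, source)
            self._cache[source] = dists
        return dists

    def distance(self, a: str, b: str) -> int:
        """Shortest path length between two genes."""
        if a not in self.graph:
            raise MissingNodeError(a)
        if b not in self.graph:
            raise MissingNodeError(b)
        # reuse whichever endpoint is already cached
        if a not in self._cache and b in self._cache:
            a, b = b, a
        dists = self.distances_from(a)
        try:
            return dists[b]
        except KeyError:
            raise ValueError(f"no path between {a!r} and {b!r}") from None


class DegreeSummary(NamedTuple):
    mean: float
    min: int
    max: int


def degree_summary(g: nx.Graph) -> DegreeSummary:
    """Mean (= 2E/N), minimum and maximum node degree."""
    if g.number_of_nodes() == 0:
        raise ValueError("cannot summarise degrees of an empty graph")
    degrees = [d for _, d in g.degree()]
    mean = 2 * g.number_of_edges() / g.number_of_nodes()
    return DegreeSummary(mean, min(degrees), max(degrees))
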