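"""Static undirected simple graphs in CSR form, with bounded breadth-first search.

The graph is the percolation substrate: nodes are 0-based integers, edges are
unordered pairs.  Adjacency is stored as a compressed sparse row structure
(``indptr``/``indices``) so that multi-source BFS over millions of nodes stays
vectorised in numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = ["Graph", "bounded_bfs"]


@dataclass
class Graph:
    """Undirected simple graph.

    Attributes
    ----------
    N : int
        Number of nodes.
    indptr, indices : ndarray
        CSR adjacency: neighbours of node ``i`` are
        ``indices[indptr[i]:indptr[i+1]]``.
    degrees : ndarray
        Per-node degree, ``indptr[i+1] - indptr[i]``.
    """

    N: int
    indptr: np.ndarray
    indices: np.ndarray
    degrees: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.degrees is None:
            self.degrees = np.diff(self.indptr).astype(np.int64)

    # ------------------------------------------------------------------ build
    @classmethod
    def from_edges(cls, n_nodes: int, u: np.ndarray, v: np.ndarray) -> "Graph":
        """Build from arrays of edge endpoints (each edge listed once)."""
        u = np.asarray(u, dtype=np.int64)
        v = np.asarray(v, dtype=np.int64)
        if u.size and (u.min() < 0 or max(u.max(), v.max()) >= n_nodes):
            raise ValueError("edge endpoint out of range")
        src = np.concatenate([u, v])
        dst = np.concatenate([v, u])
        order = np.argsort(src, kind="stable")
        src, dst = src[order], dst[order]
        degrees = np.bincount(src, minlength=n_nodes).astype(np.int64)
        indptr = np.zeros(n_nodes + 1, dtype=np.int64)
        np.cumsum(degrees, out=indptr[1:])
        return cls(N=n_nodes, indptr=indptr, indices=dst, degrees=degrees)

    @classmethod
    def from_networkx(cls, g) -> "Graph":
        nodes = sorted(g.nodes())
        if nodes != list(range(len(nodes))):
            raise ValueError("networkx graph must have nodes 0..N-1")
        edges = np.array([(a, b) for a, b in g.edges()], dtype=np.int64)
        if edges.size == 0:
            edges = np.empty((0, 2), dtype=np.int64)
        return cls.from_edges(len(nodes), edges[:, 0], edges[:, 1])

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.N))
        g.add_edges_from(self.edge_list())
        return g

    # ------------------------------------------------------------------- I/O
    @classmethod
    def read_edgelist(cls, path) -> "Graph":
        """Read a two-column whitespace-separated edge list (no header)."""
        arr = np.loadtxt(path, dtype=np.int64, ndmin=2)
        if arr.size == 0:
            raise ValueError("empty edge list")
        n = int(arr.max()) + 1
        return cls.from_edges(n, arr[:, 0], arr[:, 1])

    def write_edgelist(self, path) -> None:
        np.savetxt(path, self.edge_list(), fmt="%d")

    def edge_list(self) -> np.ndarray:
        """(E, 2) array with each undirected edge listed once, u < v."""
        src = np.repeat(np.arange(self.N, dtype=np.int64), self.degrees)
        mask = src < self.indices
        return np.column_stack([src[mask], self.indices[mask]])

    # ---------------------------------------------------------------- queries
    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i] : self.indptr[i + 1]]

    @property
    def n_edges(self) -> int:
        return int(self.indices.size // 2)

    def is_simple(self) -> bool:
        """No self-loops and no repeated neighbours."""
        for i in range(self.N):
            nb = self.neighbors(i)
            if np.any(nb == i) or np.unique(nb).size != nb.size:
                return False
        return True

    def degree_moment(self, order: int = 1) -> float:
        return float(np.mean(self.degrees.astype(float) ** order))

    def neighbors_of_set(self, frontier: np.ndarray) -> np.ndarray:
        """All neighbours (with multiplicity) of the nodes in ``frontier``."""
        counts = self.degrees[frontier]
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=self.indices.dtype)
        starts = self.indptr[frontier]
        pos = np.arange(total, dtype=np.int64)
        ends = np.cumsum(counts)
        shift = np.repeat(ends - counts, counts)
        base = np.repeat(starts, counts)
        return self.indices[base + (pos - shift)]


class _BFSWorkspace:
    """Reusable scratch arrays so repeated BFS calls avoid O(N) resets."""

    def __init__(self, graph: Graph):
        self.graph = graph
        self.token = np.zeros(graph.N, dtype=np.int64)
        self.dist = np.zeros(graph.N, dtype=np.int64)
        self.current = 0

    def run(self, sources: np.ndarray, max_dist: int):
        """Return (nodes_reached, dist_of_reached) within ``max_dist`` hops."""
        g = self.graph
        self.current += 1
        tok = self.current
        sources = np.asarray(sources, dtype=np.int64)
        if sources.size == 0:
            return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        self.token[sources] = tok
        self.dist[sources] = 0
        reached = [sources]
        dists = [np.zeros(sources.size, dtype=np.int64)]
        frontier = sources
        d = 0
        while frontier.size and d < max_dist:
            d += 1
            nxt = g.neighbors_of_set(frontier)
            if nxt.size == 0:
                break
            nxt = nxt[self.token[nxt] != tok]
            if nxt.size == 0:
                break
            nxt = np.unique(nxt)
            self.token[nxt] = tok
            self.dist[nxt] = d
            reached.append(nxt)
            dists.append(np.full(nxt.size, d, dtype=np.int64))
            frontier = nxt
        return np.concatenate(reached), np.concatenate(dists)


def bounded_bfs(
    graph: Graph, source_set: Iterable[int], max_dist: int
) -> Mapping[int, int]:
    """Hop distances from a set of sources, truncated at ``max_dist``.

    Returns a dict mapping each node within ``max_dist`` hops of the source
    set to its shortest hop distance (sources themselves at distance 0).
    Unreachable or out-of-range nodes are absent.  An empty source set gives
    an empty map.  Inactive nodes are ordinary nodes here: distances are pure
    topological hop counts on the full graph.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    sources = np.unique(np.fromiter(source_set, dtype=np.int64))
    if sources.size == 0:
        return {}
    ws = _BFSWorkspace(graph)
    nodes, dists = ws.run(sources, max_dist)
    return {int(n): int(d) for n, d in zip(nodes, dists)}
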