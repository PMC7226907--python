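"""Cumulative merging percolation (CMP) and degree-ordered percolation (DOP).

A node of degree k is *active* when k >= ka.  Every active node starts as a
cluster of mass equal to its degree.  Two clusters alpha and beta merge when
some pair of their member nodes is at hop distance

    d <= min(r(m_alpha), r(m_beta)),

i.e. each cluster must lie within the interaction range of the other (an
asymmetric situation does not merge).  Masses add on merging and the process
is iterated to its fixed point, which is independent of the processing order.
With the default range r(m) = m/ka the smallest active node has range exactly
1; with r(m) = 1 the process reduces to DOP, whose clusters are simply the
connected components of the subgraph induced by the active nodes.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .graph import Graph, _BFSWorkspace

__all__ = [
    "CMPConfig",
    "ClusterPartition",
    "NodeClassCounts",
    "activate",
    "run_dop",
    "run_cmp",
    "classify_nodes",
    "sweep_ka",
    "range_m_over_ka",
    "range_const1",
]


def range_m_over_ka(ka: int) -> Callable[[float], float]:
    """Default interaction range r(m) = m/ka (range 1 at the smallest mass)."""

    def r(m: float) -> float:
        return m / ka

    return r


def range_const1(ka: int) -> Callable[[float], float]:
    """Constant range r(m) = 1: reduces CMP to degree-ordered percolation."""
    return lambda m: 1.0


@dataclass
class CMPConfig:
    """Activation threshold and interaction-range law of a CMP process."""

    ka: int
    range_fn: Callable[[float], float] | None = None

    def __post_init__(self):
        if self.ka < 1:
            raise ValueError("ka must be >= 1")
        if self.range_fn is None:
            self.range_fn = range_m_over_ka(self.ka)


@dataclass
class ClusterPartition:
    """Limiting partition of the active nodes into CMP clusters.

    labels[i] is the cluster id of node i (clusters are labelled by their
    smallest member node id) or -1 for inactive nodes.  masses maps cluster
    id to total mass (sum of member degrees).
    """

    ka: int
    labels: np.ndarray
    masses: dict[int, float] = field(default_factory=dict)

    @property
    def membership(self) -> dict[int, int]:
        """Active-node -> cluster-id map (dict view of ``labels``)."""
        nodes = np.flatnonzero(self.labels >= 0)
        return {int(i): int(self.labels[i]) for i in nodes}

    def cluster_sizes(self) -> dict[int, int]:
        labs = self.labels[self.labels >= 0]
        ids, counts = np.unique(labs, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}

    def members(self, cid: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cid)

    def largest_cluster(self) -> tuple[int, int]:
        """(cluster id, node count) of the largest cluster; ties -> smallest id.

        Returns (-1, 0) for an empty partition.
        """
        sizes = self.cluster_sizes()
        if not sizes:
            return (-1, 0)
        best = min(sizes, key=lambda c: (-sizes[c], c))
        return best, sizes[best]

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.labels >= 0))

    def total_mass(self) -> float:
        return float(sum(self.masses.values()))


@dataclass
class NodeClassCounts:
    """Counts of the active-node classes at a given ka.

    Na = active nodes; N_iso = active nodes with no active neighbour;
    N_NI = non-isolated active nodes; N_GC_dop = nodes in the largest DOP
    cluster; N_r2 = isolated active nodes with degree >= 2 ka (range >= 2);
    N_CMP = nodes in the largest CMP cluster; S_dop/S_cmp are the largest
    cluster sizes as fractions of N.
    """

    ka: int
    Na: int
    N_iso: int
    N_NI: int
    N_GC_dop: int
    N_r2: int
    N_CMP: int
    S_dop: float
    S_cmp: float


def activate(graph: Graph, ka: int) -> np.ndarray:
    """Nodes with degree >= ka (the inclusive Theta(k - ka) convention)."""
    if ka < 1:
        raise ValueError("ka must be >= 1")
    return np.flatnonzero(graph.degrees >= ka)


class _DSU:
    """Union-find over node ids with union by size."""

    def __init__(self, nodes: np.ndarray, n: int):
        self.parent = np.arange(n, dtype=np.int64)
        self.size = np.zeros(n, dtype=np.int64)
        self.size[nodes] = 1

    def find(self, x: int) -> int:
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:  # path compression
            p[x], x = root, p[x]
        return int(root)

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return ra
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        return ra


def _labels_from_dsu(graph: Graph, active: np.ndarray, dsu: _DSU) -> ClusterPartition:
    """Relabel each cluster by its smallest member node id."""
    labels = np.full(graph.N, -1, dtype=np.int64)
    roots = np.fromiter((dsu.find(int(i)) for i in active), dtype=np.int64,
                        count=active.size)
    # smallest member id per root
    smallest: dict[int, int] = {}
    for node, rt in zip(active, roots):
        if rt not in smallest or node < smallest[rt]:
            smallest[rt] = int(node)
    masses: dict[int, float] = {}
    deg = graph.degrees
    for node, rt in zip(active, roots):
        cid = smallest[rt]
        labels[node] = cid
        masses[cid] = masses.get(cid, 0.0) + float(deg[node])
    return ClusterPartition(ka=-1, labels=labels, masses=masses)


def run_dop(graph: Graph, ka: int) -> ClusterPartition:
    """Degree-ordered percolation: components of the active induced subgraph."""
    active = activate(graph, ka)
    dsu = _DSU(active, graph.N)
    act_mask = np.zeros(graph.N, dtype=bool)
    act_mask[active] = True
    for i in active:
        nb = graph.neighbors(int(i))
        for j in nb[act_mask[nb]]:
            dsu.union(int(i), int(j))
    part = _labels_from_dsu(graph, active, dsu)
    part.ka = ka
    return part


def run_cmp(
    graph: Graph,
    config: CMPConfig,
    order: Sequence[int] | np.random.Generator | None = None,
) -> ClusterPartition:
    """Run the CMP merging process to its limiting partition.

    Maintains a work queue of clusters.  A cluster alpha of mass m is
    processed by a bounded BFS from all its member nodes to depth
    floor(r(m)) (distances are integers, so only the floor of a real range
    matters); every active node of another cluster beta found at distance d
    is merged into alpha iff d <= r(m_beta) as well (mutuality).  Merged
    clusters are re-enqueued, since a larger mass can reach new partners;
    a cluster that was blocked only by the mutuality condition re-examines
    its partners when its own mass grows.  The queue-empty fixed point is
    independent of processing order.

    ``order`` optionally permutes the initial processing order: an explicit
    sequence of active node ids, or a Generator used to shuffle (exercised by
    the order-independence tests).
    """
    ka = config.ka
    range_fn = config.range_fn
    active = activate(graph, ka)
    labels_empty = active.size == 0
    if labels_empty:
        return ClusterPartition(ka=ka, labels=np.full(graph.N, -1, dtype=np.int64))

    dsu = _DSU(active, graph.N)
    mass = np.zeros(graph.N, dtype=np.float64)
    mass[active] = graph.degrees[active]
    members: dict[int, np.ndarray] = {
        int(i): np.array([i], dtype=np.int64) for i in active
    }
    act_mask = np.zeros(graph.N, dtype=bool)
    act_mask[active] = True

    if isinstance(order, np.random.Generator):
        initial = active.copy()
        order.shuffle(initial)
    elif order is not None:
        initial = np.asarray(list(order), dtype=np.int64)
        if sorted(initial.tolist()) != sorted(active.tolist()):
            raise ValueError("order must be a permutation of the active nodes")
    else:
        initial = active
    queue: deque[int] = deque(int(i) for i in initial)
    in_queue = set(queue)
    ws = _BFSWorkspace(graph)

    while queue:
        a = queue.popleft()
        in_queue.discard(a)
        if dsu.find(a) != a:
            continue  # absorbed since enqueued
        r_a = float(range_fn(mass[a]))
        if r_a < 1.0:
            raise ValueError(f"range_fn returned {r_a} < 1 for mass {mass[a]}")
        depth = int(np.floor(r_a))
        nodes, dists = ws.run(members[a], depth)
        sel = (dists > 0) & act_mask[nodes]
        found, fdist = nodes[sel], dists[sel]
        # minimal distance to each foreign cluster
        dmin: dict[int, int] = {}
        for v, d in zip(found, fdist):
            rt = dsu.find(int(v))
            if rt == a:
                continue
            if rt not in dmin or d < dmin[rt]:
                dmin[rt] = int(d)
        merged_any = False
        for rt, d in dmin.items():
            r_b = float(range_fn(mass[rt]))
            if r_b < 1.0:
                raise ValueError(f"range_fn returned {r_b} < 1 for mass {mass[rt]}")
            if d <= r_b:  # d <= r_a is guaranteed by the BFS depth
                new_root = dsu.union(a, rt)
                other = rt if new_root == a else a
                if new_root != a:
                    # keep processing under the surviving root
                    a = new_root
                mass[new_root] = mass[new_root] + mass[other]
                members[new_root] = np.concatenate(
                    [members[new_root], members.pop(other)]
                )
                merged_any = True
        if merged_any and a not in in_queue:
            queue.append(a)
            in_queue.add(a)

    part = _labels_from_dsu(graph, active, dsu)
    part.ka = ka
    return part


def _has_active_neighbor(graph: Graph, active: np.ndarray, act_mask: np.ndarray):
    """Boolean array aligned with ``active``: any neighbour active?"""
    if active.size == 0:
        return np.zeros(0, dtype=bool)
    nbrs = graph.neighbors_of_set(active)
    flags = act_mask[nbrs].astype(np.int64)
    counts = graph.degrees[active]
    ends = np.cumsum(counts)
    starts = ends - counts
    nonempty = counts > 0
    out = np.zeros(active.size, dtype=bool)
    if np.any(nonempty):
        sums = np.add.reduceat(flags, starts[nonempty])
        out[nonempty] = sums > 0
    return out


def classify_nodes(
    graph: Graph,
    ka: int,
    cmp_partition: ClusterPartition,
    dop_partition: ClusterPartition,
) -> NodeClassCounts:
    """Count the active-node classes entering the cluster accounting.

    Raises if the two partitions were computed at different ka.
    """
    if cmp_partition.ka != ka or dop_partition.ka != ka:
        raise ValueError("partitions were not computed at the requested ka")
    active = activate(graph, ka)
    act_mask = np.zeros(graph.N, dtype=bool)
    act_mask[active] = True
    has_nb = _has_active_neighbor(graph, active, act_mask)
    n_a = int(active.size)
    n_ni = int(has_nb.sum())
    n_iso = n_a - n_ni
    iso_nodes = active[~has_nb]
    n_r2 = int(np.count_nonzero(graph.degrees[iso_nodes] >= 2 * ka))
    _, n_gc_dop = dop_partition.largest_cluster()
    _, n_cmp = cmp_partition.largest_cluster()
    # a lone active node is not a giant component: without at least one
    # merge there is no cluster to speak of (keeps N_GC_dop <= N_NI)
    n_gc_dop = n_gc_dop if n_gc_dop >= 2 else 0
    n_cmp = n_cmp if n_cmp >= 2 else 0
    return NodeClassCounts(
        ka=ka,
        Na=n_a,
        N_iso=n_iso,
        N_NI=n_ni,
        N_GC_dop=n_gc_dop,
        N_r2=n_r2,
        N_CMP=n_cmp,
        S_dop=n_gc_dop / graph.N,
        S_cmp=n_cmp / graph.N,
    )


def sweep_ka(
    graph: Graph,
    ka_values: Sequence[int],
    range_kind: str | Callable[[int], Callable[[float], float]] = "m_over_ka",
) -> pd.DataFrame:
    """Run DOP + CMP and the node-class accounting over a grid of ka values.

    ``ka_values`` must be sorted ascending.  ``range_kind`` is ``"m_over_ka"``
    (default), ``"const1"``, or a callable ka -> range function.  Returns one
    row per ka with all class counts and both giant-cluster fractions.
    """
    ka_values = list(ka_values)
    if ka_values != sorted(ka_values):
        raise ValueError("ka_values must be sorted ascending")
    if callable(range_kind):
        factory = range_kind
    elif range_kind == "m_over_ka":
        factory = range_m_over_ka
    elif range_kind == "const1":
        factory = range_const1
    else:
        raise ValueError("range_kind must be 'm_over_ka', 'const1' or callable")
    rows = []
    for ka in ka_values:
        dop = run_dop(graph, ka)
        cmp_part = run_cmp(graph, CMPConfig(ka=ka, range_fn=factory(ka)))
        counts = classify_nodes(graph, ka, cmp_part, dop)
        rows.append(vars(counts))
    return pd.DataFrame(rows)
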