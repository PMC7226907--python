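"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the CMP oracle scans
all cluster pairs against the merge condition until no merge applies, using
networkx all-pairs shortest paths; the SIS oracle solves the absorbing
continuous-time Markov chain exactly.
"""

import itertools

import networkx as nx
import numpy as np


def brute_cmp_partition(graph, ka, range_fn):
    """Fixed point of pairwise merging: frozensets of member nodes."""
    nxg = graph.to_networkx()
    dist = dict(nx.all_pairs_shortest_path_length(nxg))
    active = [i for i in range(graph.N) if graph.degrees[i] >= ka]
    clusters = [{i} for i in active]
    masses = [float(graph.degrees[i]) for i in active]
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(range(len(clusters)), 2):
            if clusters[a] is None or clusters[b] is None:
                continue
            d = min(
                dist[i].get(j, 10**9)
                for i in clusters[a]
                for j in clusters[b]
            )
            if d <= min(range_fn(masses[a]), range_fn(masses[b])):
                clusters[a] |= clusters[b]
                masses[a] += masses[b]
                clusters[b] = None
                changed = True
    return sorted(
        (frozenset(c) for c in clusters if c is not None),
        key=lambda s: min(s),
    )


def partition_as_sets(partition):
    """ClusterPartition -> sorted list of frozensets of member nodes."""
    return sorted(
        (frozenset(np.flatnonzero(partition.labels == cid).tolist())
         for cid in partition.masses),
        key=lambda s: min(s),
    )


def exact_mean_extinction_time(edges, n, lam, initial_state):
    """Mean SIS extinction time from an absorbing-CTMC linear solve.

    States are bitmasks over n nodes (bit i set = node i infected); recovery
    rate 1 per infected node, infection rate lam per S-I edge.  Returns the
    expected time to reach the all-susceptible state from ``initial_state``.
    """
    size = 2**n
    Q = np.zeros((size, size))
    for st in range(size):
        for i in range(n):
            if st >> i & 1:
                Q[st, st & ~(1 << i)] += 1.0
        for a, b in edges:
            for i, j in ((a, b), (b, a)):
                if st >> i & 1 and not st >> j & 1:
                    Q[st, st | 1 << j] += lam
        Q[st, st] = -Q[st].sum()
    transient = [st for st in range(size) if st != 0]
    tau = np.linalg.solve(Q[np.ix_(transient, transient)], -np.ones(len(transient)))
    return float(tau[transient.index(initial_state)])
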