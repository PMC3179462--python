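"""Independent brute-force oracles used to validate the package's graph
metrics on small graphs.  Deliberately naive: Floyd-Warshall distances,
exhaustive simple-path enumeration, explicit node deletion, direct
partition tallies, and exhaustive set-partition search.
"""

from __future__ import annotations

import itertools

import numpy as np

import connectome_backbone as cb


def floyd_warshall(g: cb.BackboneGraph) -> np.ndarray:
    n = g.n_nodes
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i, j in g.edges:
        d[i, j] = d[j, i] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k][:, None] + d[k, :][None, :])
    return d


def brute_global_efficiency(g: cb.BackboneGraph) -> float:
    d = floyd_warshall(g)
    n = g.n_nodes
    tot = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                tot += 1.0 / d[i, j]
    return tot / (n * (n - 1))


def brute_local_efficiency(g: cb.BackboneGraph) -> float:
    nbr = g.neighbors()
    vals = []
    for i in range(g.n_nodes):
        if len(nbr[i]) < 2:
            vals.append(0.0)
        else:
            vals.append(brute_global_efficiency(g.subgraph(nbr[i])))
    return float(np.mean(vals))


def all_shortest_paths(g: cb.BackboneGraph, j: int, k: int) -> list[tuple[int, ...]]:
    """Every shortest simple path from j to k, by exhaustive enumeration."""
    if j == k:
        return [(j,)]
    nbr = g.neighbors()
    best: list[tuple[int, ...]] = []
    best_len = np.inf
    stack = [(j, (j,))]
    while stack:
        v, path = stack.pop()
        if len(path) - 1 > best_len:
            continue
        for w in nbr[v]:
            if w in path:
                continue
            new = path + (w,)
            if w == k:
                if len(new) - 1 < best_len:
                    best_len = len(new) - 1
                    best = [new]
                elif len(new) - 1 == best_len:
                    best.append(new)
            else:
                stack.append((w, new))
    return best


def brute_betweenness(g: cb.BackboneGraph) -> np.ndarray:
    n = g.n_nodes
    b = np.zeros(n)
    for j, k in itertools.combinations(range(n), 2):
        paths = all_shortest_paths(g, j, k)
        if not paths:
            continue
        for i in range(n):
            if i in (j, k):
                continue
            through = sum(1 for p in paths if i in p[1:-1])
            b[i] += through / len(paths)
    return b / ((n - 1) * (n - 2) / 2)


def brute_vulnerability(g: cb.BackboneGraph) -> np.ndarray:
    e0 = brute_global_efficiency(g)
    v = np.zeros(g.n_nodes)
    for i in range(g.n_nodes):
        v[i] = (e0 - brute_global_efficiency(g.remove_node(i))) / e0
    return v


def brute_modularity(g: cb.BackboneGraph, labels) -> float:
    labels = np.asarray(labels)
    ll = g.n_edges
    q = 0.0
    for s in np.unique(labels):
        members = set(np.flatnonzero(labels == s).tolist())
        l_s = sum(1 for i, j in g.edges if i in members and j in members)
        d_s = sum(g.degree[i] for i in members)
        q += l_s / ll - (d_s / (2 * ll)) ** 2
    return q


def set_partitions(items: list[int]):
    """All partitions of a list (restricted Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [part[k] + [first]] + part[k + 1:]
        yield part + [[first]]


def exhaustive_max_modularity(g: cb.BackboneGraph) -> float:
    best = -np.inf
    labels = np.zeros(g.n_nodes, dtype=int)
    for part in set_partitions(list(range(g.n_nodes))):
        for m, block in enumerate(part):
            labels[block] = m
        best = max(best, brute_modularity(g, labels))
    return best
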