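"""Efficiency, cost, betweenness and vulnerability of an unweighted graph.

Global efficiency is the mean inverse shortest-path length over ordered
node pairs (disconnected pairs contribute 0); local efficiency is the
mean, over nodes, of the global efficiency of each node's
neighbor-induced subgraph (the node itself excluded).  A small-world
network combines high local efficiency (cliquish neighborhoods) with
high global efficiency (short paths) at low cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import BackboneGraph, PathStats, shortest_paths


def _bfs_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs hop distances of a boolean adjacency matrix.

    Level-synchronous BFS run for all sources at once via boolean
    matrix products; disconnected pairs stay at inf.
    """
    n = adj.shape[0]
    dist = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    reach = adj | np.eye(n, dtype=bool)
    d = 1
    while True:
        new_reach = reach @ adj | reach
        newly = new_reach & ~reach
        if not newly.any():
            return dist
        d += 1
        dist[newly] = d
        reach = new_reach


def _mean_inv_dist(dist: np.ndarray) -> float:
    """Mean of 1/d over ordered off-diagonal pairs (disconnected -> 0)."""
    n = dist.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0  # diagonal zeros and disconnected pairs
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(g: BackboneGraph, paths: PathStats | None = None) -> float:
    """E_glob = (1/(N(N-1))) * sum_{i != j} 1/d_ij, in [0, 1]."""
    if g.n_nodes < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    dist = paths.dist if paths is not None else _bfs_distances(g.adjacency().astype(bool))
    return _mean_inv_dist(dist)


def nodal_efficiency(g: BackboneGraph, paths: PathStats | None = None) -> np.ndarray:
    """Per-node mean inverse distance to the other N-1 nodes."""
    dist = paths.dist if paths is not None else _bfs_distances(g.adjacency().astype(bool))
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    return inv.sum(axis=1) / (g.n_nodes - 1)


def local_efficiency(g: BackboneGraph) -> tuple[float, np.ndarray]:
    """E_loc and the per-node subgraph efficiencies.

    Node i's contribution is the global efficiency of the subgraph induced
    by its neighbors, normalized by that subgraph's own node count; nodes
    of degree <= 1 contribute 0 (their neighbor subgraph has < 2 nodes).
    """
    adj = g.adjacency().astype(bool)
    per_node = np.zeros(g.n_nodes)
    for i in range(g.n_nodes):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size >= 2:
            per_node[i] = _mean_inv_dist(_bfs_distances(adj[np.ix_(nbrs, nbrs)]))
    return float(per_node.mean()), per_node


def network_cost(g: BackboneGraph) -> float:
    """Fraction of possible edges present: |E| / (N(N-1)/2)."""
    if g.n_nodes < 2:
        raise ValueError("cost needs at least 2 nodes")
    return g.n_edges / g.max_edges


def betweenness(g: BackboneGraph, paths: PathStats | None = None) -> np.ndarray:
    """Normalized betweenness centrality per node, in [0, 1].

    B_i sums, over unordered pairs {j, k} not containing i, the fraction
    of j-k shortest paths that pass through i, normalized by
    (N-1)(N-2)/2 so a star hub attains exactly 1.  Disconnected pairs
    (sigma_jk = 0) contribute 0.
    """
    n = g.n_nodes
    if n < 3:
        raise ValueError("betweenness needs at least 3 nodes")
    if paths is None:
        paths = shortest_paths(g)
    norm = (n - 1) * (n - 2) / 2
    b = np.zeros(n)
    sigma = paths.sigma
    for i in range(n):
        cnt = paths.through(i)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(sigma > 0, cnt / sigma, 0.0)
        b[i] = np.triu(frac, k=1).sum() / norm
    return b


def vulnerability(g: BackboneGraph) -> np.ndarray:
    """Relative drop in global efficiency when each node is removed.

    V_i = (E_glob - E_glob^{-i}) / E_glob, where E_glob^{-i} is computed
    on the remaining N-1 nodes with their own normalization.  Can be
    negative: removing a peripheral node may raise the normalized
    efficiency of what remains.
    """
    if g.n_nodes < 3:
        raise ValueError("vulnerability needs at least 3 nodes")
    e0 = global_efficiency(g)
    if e0 == 0:
        raise ValueError("vulnerability undefined for zero-efficiency graph")
    adj = g.adjacency().astype(bool)
    keep = np.arange(g.n_nodes)
    v = np.zeros(g.n_nodes)
    for i in range(g.n_nodes):
        rest = keep[keep != i]
        e_i = _mean_inv_dist(_bfs_distances(adj[np.ix_(rest, rest)]))
        v[i] = (e0 - e_i) / e0
    return v


@dataclass
class EfficiencyReport:
    """Efficiency/cost summary of one backbone graph."""

    e_glob: float
    e_loc: float
    cost: float
    nodal_e_glob: np.ndarray
    nodal_e_loc: np.ndarray


def efficiency_report(g: BackboneGraph) -> EfficiencyReport:
    paths = shortest_paths(g)
    e_loc, per_node_loc = local_efficiency(g)
    return EfficiencyReport(
        e_glob=global_efficiency(g, paths),
        e_loc=e_loc,
        cost=network_cost(g),
        nodal_e_glob=nodal_efficiency(g, paths),
        nodal_e_loc=per_node_loc,
    )


@dataclass
class CentralityTable:
    """Per-node betweenness and vulnerability of one backbone graph."""

    betweenness: np.ndarray
    vulnerability: np.ndarray


def centrality_table(g: BackboneGraph) -> CentralityTable:
    return CentralityTable(betweenness=betweenness(g), vulnerability=vulnerability(g))
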