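"""Modularity, greedy community detection, and node-role cartography.

Modularity Q of a partition is the excess of the within-module edge
fraction over its degree-based random expectation,
Q = sum_s [ l_s/L - (d_s/(2L))^2 ].  Communities are found with the
agglomerative fast-greedy (Clauset-Newman-Moore style) optimizer.  Node
roles follow the z-P cartography: the within-module degree z-score
separates module hubs (z > 2.5) from non-hubs, and the participation
coefficient P = 1 - sum_s (kappa_is/k_i)^2 grades how evenly a node's
edges spread over modules, yielding role letters A-G.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .backbone import SNRMatrix, threshold_to_cost
from .graph import BackboneGraph
from .null_models import rewired_ensemble


@dataclass
class ModulePartition:
    """Node -> module assignment with modularity bookkeeping.

    ``l_s`` counts intra-module edges, ``d_s`` sums member degrees;
    module ids are 0..M-1 in order of each module's smallest node.
    """

    assignment: np.ndarray
    q: float
    l_s: np.ndarray
    d_s: np.ndarray
    n_edges: int

    @property
    def n_modules(self) -> int:
        return len(self.l_s)

    def members(self, module: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == module)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel modules 0..M-1 by order of first (smallest-index) member."""
    remap: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, m in enumerate(labels):
        if m not in remap:
            remap[m] = len(remap)
        out[i] = remap[m]
    return out


def partition_from_labels(g: BackboneGraph, labels) -> ModulePartition:
    """Build a ModulePartition (with Q) from an arbitrary node labelling."""
    labels = _canonical_labels(np.asarray(labels))
    if labels.shape != (g.n_nodes,):
        raise ValueError("one module label per node required")
    if g.n_edges == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    m = labels.max() + 1
    l_s = np.zeros(m, dtype=np.int64)
    for i, j in g.edges:
        if labels[i] == labels[j]:
            l_s[labels[i]] += 1
    d_s = np.bincount(labels, weights=g.degree, minlength=m).astype(np.int64)
    ll = g.n_edges
    q = float((l_s / ll - (d_s / (2 * ll)) ** 2).sum())
    return ModulePartition(assignment=labels, q=q, l_s=l_s, d_s=d_s, n_edges=ll)


def modularity(g: BackboneGraph, labels) -> float:
    """Q = sum_s [ l_s/L - (d_s/(2L))^2 ] for the given partition."""
    return partition_from_labels(g, labels).q


def detect_communities(g: BackboneGraph) -> ModulePartition:
    """Fast-greedy agglomerative modularity optimization.

    Starts from singleton communities, repeatedly merges the connected
    community pair with the largest modularity gain
    dQ = l_uv/L - 2 (d_u/2L)(d_v/2L), tracks the best Q seen along the
    merge path, and returns that partition.  Ties are broken by the
    lowest community-id pair (ids are the smallest member node index), so
    the result is deterministic.  Components agglomerate independently;
    isolated nodes stay singleton modules.
    """
    if g.n_edges == 0:
        raise ValueError("community detection needs at least one edge")
    ll = g.n_edges
    # community id = smallest member node; state per live community
    comm_of = list(range(g.n_nodes))
    deg = {i: int(g.degree[i]) for i in range(g.n_nodes)}
    intra = {i: 0 for i in range(g.n_nodes)}
    between: dict[int, dict[int, int]] = {i: {} for i in range(g.n_nodes)}
    for i, j in g.edges:
        between[i][j] = between[i].get(j, 0) + 1
        between[j][i] = between[j].get(i, 0) + 1

    def q_now() -> float:
        return sum(
            intra[c] / ll - (deg[c] / (2 * ll)) ** 2 for c in intra
        )

    best_q = q_now()
    best_labels = np.array(comm_of)

    while True:
        best = None  # (-dq, u, v)
        for u in sorted(between):
            for v in sorted(between[u]):
                if v <= u:
                    continue
                dq = between[u][v] / ll - 2 * (deg[u] / (2 * ll)) * (deg[v] / (2 * ll))
                cand = (-dq, u, v)
                if best is None or cand < best:
                    best = cand
        if best is None:
            break
        _, u, v = best  # merge v into u (u < v)
        intra[u] += intra.pop(v) + between[u].pop(v)
        deg[u] += deg.pop(v)
        del between[v][u]
        for w, cnt in between.pop(v).items():
            del between[w][v]
            between[u][w] = between[u].get(w, 0) + cnt
            between[w][u] = between[u][w]
        for i in range(g.n_nodes):
            if comm_of[i] == v:
                comm_of[i] = u
        q = q_now()
        if q > best_q + 1e-12:
            best_q = q
            best_labels = np.array(comm_of)

    return partition_from_labels(g, best_labels)


@dataclass(frozen=True)
class RoleThresholds:
    """z-P plane boundaries of the role cartography (configurable)."""

    z_hub: float = 2.5
    p_nonhub: tuple[float, float, float] = (0.05, 0.62, 0.80)  # A|B|C|D
    p_hub: tuple[float, float] = (0.30, 0.75)                  # E|F|G


def node_roles(
    g: BackboneGraph,
    partition: ModulePartition,
    thresholds: RoleThresholds = RoleThresholds(),
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Per-node z, P and role letter under a module partition.

    z_i standardizes the intra-modular degree kappa_i against its
    module's mean and SD (z = 0 when the module SD is 0); P_i is the
    participation coefficient.  Degree-0 nodes get P = 0, role A, and
    ``degenerate=True``.

    Returns a DataFrame with columns
    ``degree, kappa, z, p, role, degenerate`` indexed by node (or by the
    given labels).
    """
    assign = partition.assignment
    m = partition.n_modules
    kappa_to = np.zeros((g.n_nodes, m))
    for i, j in g.edges:
        kappa_to[i, assign[j]] += 1
        kappa_to[j, assign[i]] += 1
    kappa = kappa_to[np.arange(g.n_nodes), assign]
    k = g.degree.astype(float)

    z = np.zeros(g.n_nodes)
    for s in range(m):
        mem = assign == s
        mu = kappa[mem].mean()
        sd = kappa[mem].std()  # population SD; 0 -> z stays 0
        if sd > 0:
            z[mem] = (kappa[mem] - mu) / sd

    degenerate = k == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 1.0 - np.nansum((kappa_to / np.where(k > 0, k, np.nan)[:, None]) ** 2, axis=1)
    p[degenerate] = 0.0

    a, b, c = thresholds.p_nonhub
    e, f = thresholds.p_hub
    roles = []
    for zi, pi, dg in zip(z, p, degenerate):
        if dg:
            roles.append("A")
        elif zi > thresholds.z_hub:
            roles.append("E" if pi <= e else "F" if pi <= f else "G")
        else:
            roles.append("A" if pi <= a else "B" if pi <= b else "C" if pi <= c else "D")

    idx = labels if labels is not None else list(range(g.n_nodes))
    return pd.DataFrame(
        {
            "degree": g.degree,
            "kappa": kappa,
            "z": z,
            "p": p,
            "role": roles,
            "degenerate": degenerate,
        },
        index=idx,
    )


def nonrandom_modularity_sweep(
    snr: SNRMatrix,
    costs: list[float],
    n_null: int = 100,
    seed: int = 0,
    n_swap_factor: float = 10.0,
) -> list[dict[str, float]]:
    """Detected Q of the backbone vs rewired-null detected Q, per cost."""
    out = []
    for ci, cost in enumerate(costs):
        g = threshold_to_cost(snr, cost)
        q_brain = detect_communities(g).q
        ens = rewired_ensemble(g, n_null, n_swap_factor, seed=seed + 1000 * ci)
        q_null = np.array([detect_communities(r).q for r in ens.realizations])
        out.append(
            {
                "cost": cost,
                "q_brain": q_brain,
                "q_random_mean": float(q_null.mean()),
                "q_random_sd": float(q_null.std(ddof=1)) if n_null > 1 else 0.0,
            }
        )
    return out
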