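"""Null models: degree-preserving rewired ensembles and matched ring lattices.

The small-world verdict compares a backbone against (a) random networks
with the same number of nodes, edges AND the same degree sequence
(generated by repeated double-edge swaps) and (b) a regular ring lattice
with the same number of nodes and edges.  A small-world network has local
efficiency above the rewired ensemble and global efficiency above the
lattice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import SNRMatrix, threshold_to_cost
from .graph import BackboneGraph, _canon
from .metrics import global_efficiency, local_efficiency


def rewire_preserving_degrees(
    g: BackboneGraph,
    n_swap_factor: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> BackboneGraph:
    """Randomize a graph by double-edge swaps, preserving every degree.

    Attempts ``n_swap_factor * |E|`` swaps (a-b, c-d) -> (a-d, c-b),
    rejecting any move that would create a self-loop or duplicate edge.
    Graphs with no legal swap (e.g. a star) come back unchanged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = sorted(g.edges)
    if len(edges) < 2:
        return g
    edge_set = set(edges)
    n_attempts = int(round(n_swap_factor * len(edges)))
    for _ in range(n_attempts):
        k1, k2 = rng.integers(0, len(edges), size=2)
        if k1 == k2:
            continue
        a, b = edges[k1]
        c, d = edges[k2]
        if len({a, b, c, d}) < 4:
            continue
        e1, e2 = _canon(a, d), _canon(c, b)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard((a, b))
        edge_set.discard((c, d))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[k1] = e1
        edges[k2] = e2
    return BackboneGraph(g.n_nodes, frozenset(edge_set))


def matched_lattice(n: int, n_edges: int) -> BackboneGraph:
    """Ring lattice with ``n`` nodes and exactly ``n_edges`` edges.

    Edges are added in increasing circular distance (the distance-1 ring
    first, then distance-2 chords, ...), within a tier in increasing
    lower endpoint — deterministic and rotation-equivariant.
    """
    k_max = n * (n - 1) // 2
    if not 0 <= n_edges <= k_max:
        raise ValueError(f"n_edges must be in [0, {k_max}]")
    edges: list[tuple[int, int]] = []
    for dist in range(1, n // 2 + 1):
        limit = n if 2 * dist != n else n // 2  # opposite chords counted once
        for i in range(limit):
            if len(edges) == n_edges:
                return BackboneGraph.from_edges(n, edges)
            edges.append(_canon(i, (i + dist) % n))
    return BackboneGraph.from_edges(n, edges)


@dataclass
class NullEnsemble:
    """Degree-preserving rewired realizations of a reference graph."""

    realizations: list[BackboneGraph]
    kind: str
    seed: int


def rewired_ensemble(
    g: BackboneGraph,
    n_null: int = 100,
    n_swap_factor: float = 10.0,
    seed: int = 0,
) -> NullEnsemble:
    rng = np.random.default_rng(seed)
    reals = [rewire_preserving_degrees(g, n_swap_factor, rng) for _ in range(n_null)]
    return NullEnsemble(realizations=reals, kind="rewired", seed=seed)


def smallworld_sweep(
    snr: SNRMatrix,
    costs: list[float],
    n_null: int = 100,
    seed: int = 0,
    n_swap_factor: float = 10.0,
) -> list[dict[str, float | bool]]:
    """Efficiency of backbone vs rewired nulls vs matched lattice per cost.

    Returns one record per cost with the backbone's E_glob/E_loc, the
    rewired-ensemble mean and SD of both, the lattice values, and the
    small-world flag: E_loc above the rewired mean AND E_glob above the
    lattice.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    out = []
    for ci, cost in enumerate(costs):
        g = threshold_to_cost(snr, cost)
        ens = rewired_ensemble(g, n_null, n_swap_factor, seed=seed + 1000 * ci)
        eg_r = np.array([global_efficiency(r) for r in ens.realizations])
        el_r = np.array([local_efficiency(r)[0] for r in ens.realizations])
        lat = matched_lattice(g.n_nodes, g.n_edges)
        rec = {
            "cost": cost,
            "e_glob": global_efficiency(g),
            "e_loc": local_efficiency(g)[0],
            "e_glob_random_mean": float(eg_r.mean()),
            "e_glob_random_sd": float(eg_r.std(ddof=1)) if n_null > 1 else 0.0,
            "e_loc_random_mean": float(el_r.mean()),
            "e_loc_random_sd": float(el_r.std(ddof=1)) if n_null > 1 else 0.0,
            "e_glob_lattice": global_efficiency(lat),
            "e_loc_lattice": local_efficiency(lat)[0],
        }
        rec["small_world"] = bool(
            rec["e_loc"] > rec["e_loc_random_mean"]
            and rec["e_glob"] > rec["e_glob_lattice"]
        )
        out.append(rec)
    return out
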