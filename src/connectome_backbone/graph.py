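"""Unweighted undirected graph core: representation, BFS path statistics,
connected components, and Pajek export.

All node indices are 0-based internally; formats that demand 1-based ids
(Pajek) convert at the boundary.  Disconnected pairs carry an infinite
distance, which every ``1/d`` sum treats as a zero contribution.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


Edge = tuple[int, int]


def _canon(i: int, j: int) -> Edge:
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class BackboneGraph:
    """A simple undirected unweighted graph over ``n_nodes`` regions.

    Invariants: no self-loops, no duplicate edges, sum of degrees equals
    twice the edge count.
    """

    n_nodes: int
    edges: frozenset[Edge]
    degree: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("graph needs at least one node")
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop at node {i}")
            if not (0 <= i < j < self.n_nodes):
                raise ValueError(f"edge {(i, j)} not canonical / out of range")
            deg[i] += 1
            deg[j] += 1
        object.__setattr__(self, "degree", deg)

    @classmethod
    def from_edges(cls, n_nodes: int, edges: Iterable[Sequence[int]]) -> "BackboneGraph":
        return cls(n_nodes, frozenset(_canon(int(i), int(j)) for i, j in edges))

    @classmethod
    def from_adjacency(cls, adj: np.ndarray) -> "BackboneGraph":
        adj = np.asarray(adj)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        ii, jj = np.nonzero(np.triu(adj, k=1))
        return cls(adj.shape[0], frozenset(zip(ii.tolist(), jj.tolist())))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def max_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int8)
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1
        return a

    def neighbors(self) -> list[list[int]]:
        nbr: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, j in self.edges:
            nbr[i].append(j)
            nbr[j].append(i)
        return [sorted(ns) for ns in nbr]

    def subgraph(self, nodes: Sequence[int]) -> "BackboneGraph":
        """Induced subgraph, re-indexed to ``0..len(nodes)-1`` in given order."""
        pos = {n: k for k, n in enumerate(nodes)}
        keep = frozenset(
            _canon(pos[i], pos[j]) for i, j in self.edges if i in pos and j in pos
        )
        return BackboneGraph(len(nodes), keep)

    def remove_node(self, node: int) -> "BackboneGraph":
        """Graph with ``node`` and its edges deleted (re-indexed to N-1 nodes)."""
        keep = [n for n in range(self.n_nodes) if n != node]
        return self.subgraph(keep)


@dataclass
class PathStats:
    """All-pairs shortest-path statistics of an unweighted graph.

    ``dist[j, k]`` is the hop count (``inf`` when disconnected),
    ``sigma[j, k]`` the number of distinct shortest paths (0 when
    disconnected, 1 on the diagonal by convention of the empty path).
    """

    dist: np.ndarray
    sigma: np.ndarray

    def through(self, i: int) -> np.ndarray:
        """sigma_jk(i): shortest j-k paths passing through interior node i.

        Uses the counting identity sigma_jk(i) = sigma_ji * sigma_ik when
        d(j,i) + d(i,k) = d(j,k), else 0.  Rows/columns j = i or k = i are 0
        (endpoints are not interior).
        """
        d, s = self.dist, self.sigma
        on_path = d[:, i][:, None] + d[i, :][None, :] == d
        cnt = np.where(on_path, s[:, i][:, None] * s[i, :][None, :], 0.0)
        cnt[i, :] = 0.0
        cnt[:, i] = 0.0
        np.fill_diagonal(cnt, 0.0)
        return cnt


def shortest_paths(g: BackboneGraph) -> PathStats:
    """BFS all-pairs distances and shortest-path counts.

    Disconnected pairs get ``dist = inf`` and ``sigma = 0``.
    """
    n = g.n_nodes
    nbr = g.neighbors()
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in range(n):
        d = dist[s]
        sg = sigma[s]
        d[s] = 0.0
        sg[s] = 1.0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            for w in nbr[v]:
                if np.isinf(d[w]):
                    d[w] = d[v] + 1
                    queue.append(w)
                if d[w] == d[v] + 1:
                    sg[w] += sg[v]
    return PathStats(dist=dist, sigma=sigma)


def connected_components(g: BackboneGraph) -> list[list[int]]:
    """Connected node sets, largest first (ties by smallest member)."""
    nbr = g.neighbors()
    seen = [False] * g.n_nodes
    comps: list[list[int]] = []
    for s in range(g.n_nodes):
        if seen[s]:
            continue
        comp = [s]
        seen[s] = True
        queue = deque([s])
        while queue:
            v = queue.popleft()
            for w in nbr[v]:
                if not seen[w]:
                    seen[w] = True
                    comp.append(w)
                    queue.append(w)
        comps.append(sorted(comp))
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def largest_component_size(g: BackboneGraph) -> int:
    """Size of the biggest connected component; equals N iff no node is isolated
    from the rest (a fully connected network)."""
    return len(connected_components(g)[0])


def write_pajek(
    g: BackboneGraph,
    labels: Sequence[str],
    path: str | Path,
    partition: Sequence[int] | None = None,
) -> None:
    """Write a Pajek ``.net`` file (and ``.clu`` companion for a partition).

    Vertices are 1-based with quoted labels; edges are 1-based endpoint
    pairs.  ``partition`` maps node index -> module id; module ids are
    written 1-based in node order to ``<path stem>.clu``.
    """
    if len(labels) != g.n_nodes:
        raise ValueError("one label per node required")
    path = Path(path)
    lines = [f"*Vertices {g.n_nodes}"]
    lines += [f'{i + 1} "{lab}"' for i, lab in enumerate(labels)]
    lines.append("*Edges")
    lines += [f"{i + 1} {j + 1}" for i, j in sorted(g.edges)]
    path.write_text("\n".join(lines) + "\n")
    if partition is not None:
        if len(partition) != g.n_nodes:
            raise ValueError("one module id per node required")
        ids = sorted(set(partition))
        remap = {m: k + 1 for k, m in enumerate(ids)}
        clu = [f"*Vertices {g.n_nodes}"]
        clu += [str(remap[m]) for m in partition]
        path.with_suffix(".clu").write_text("\n".join(clu) + "\n")


def read_pajek(path: str | Path) -> tuple[BackboneGraph, list[str]]:
    """Minimal Pajek ``.net`` reader (round-trip partner of write_pajek)."""
    lines = Path(path).read_text().splitlines()
    labels: list[str] = []
    edges: list[Edge] = []
    n = 0
    mode = ""
    for line in lines:
        line = line.strip()
        if not line:
            continue
        low = line.lower()
        if low.startswith("*vertices"):
            n = int(line.split()[1])
            mode = "v"
        elif low.startswith("*edges"):
            mode = "e"
        elif mode == "v":
            _, rest = line.split(" ", 1)
            labels.append(rest.strip().strip('"'))
        elif mode == "e":
            a, b = line.split()[:2]
            edges.append(_canon(int(a) - 1, int(b) - 1))
    return BackboneGraph.from_edges(n, edges), labels
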