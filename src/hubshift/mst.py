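"""Minimum spanning tree of strongest connections and hub centrality.

The "minimum spanning tree" of an EEG connectivity analysis is the
spanning tree over the *strongest* connections: Kruskal's algorithm run
on edges sorted by descending PLI (equivalently, the classical MST under
any strictly decreasing transform of the weights, e.g. 1 - PLI; the edge
set is identical).  Ties in PLI are broken by ascending (i, j) index
order so the tree is deterministic.

Hub strength of a node is its betweenness centrality on the tree: the
number of unordered node pairs {s, t} (s != v != t) whose unique tree
path passes through v, divided by a normalizing pair count.  The default
denominator is N(N-1)/2, the total number of paths between any two
nodes; the more common (N-1)(N-2)/2 normalization (pairs excluding the
node itself) is available via ``denominator="interior"``.

On a tree the pair count through v has a closed form: removing v splits
the tree into components of sizes ``m_1..m_k``, and the pairs running
through v are C(N-1, 2) - sum_i C(m_i, 2).  This is exact in integer
arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .montage import Montage, REGION_NAMES

__all__ = ["SpanningTree", "CentralityVector", "build_mst", "betweenness", "regional_bc"]


@dataclass(frozen=True)
class SpanningTree:
    """A spanning tree as an edge list of (i, j, weight), i < j."""

    n_nodes: int
    edges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        if len(self.edges) != self.n_nodes - 1:
            raise ValueError(
                f"a spanning tree on {self.n_nodes} nodes needs "
                f"{self.n_nodes - 1} edges, got {len(self.edges)}"
            )

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, j, _ in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def to_frame(self, montage: Montage | None = None):
        import pandas as pd

        rows = []
        for i, j, w in self.edges:
            if montage is not None:
                rows.append((montage.channels[i], montage.channels[j], w))
            else:
                rows.append((i, j, w))
        return pd.DataFrame(rows, columns=["chan_i", "chan_j", "pli"])


@dataclass(frozen=True)
class CentralityVector:
    """Per-node betweenness centrality and its normalization convention."""

    bc: np.ndarray
    denominator: str  # "pairs" (N(N-1)/2) or "interior" ((N-1)(N-2)/2)
    raw_counts: np.ndarray  # integer pair counts through each node


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_mst(matrix) -> SpanningTree:
    """Kruskal over edges by descending weight, ties by ascending (i, j).

    Accepts a ConnectivityMatrix or a plain symmetric array.
    """
    values = np.asarray(getattr(matrix, "values", matrix), dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if np.any(np.isnan(values)):
        raise ValueError("connectivity matrix contains NaN")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError("connectivity matrix is not symmetric")
    iu = np.triu_indices(n, k=1)
    order = sorted(
        zip(iu[0].tolist(), iu[1].tolist()),
        key=lambda ij: (-values[ij[0], ij[1]], ij[0], ij[1]),
    )
    uf = _UnionFind(n)
    edges: list[tuple[int, int, float]] = []
    for i, j in order:
        if uf.union(i, j):
            edges.append((i, j, float(values[i, j])))
            if len(edges) == n - 1:
                break
    if len(edges) != n - 1:
        raise ValueError("matrix does not describe a connected graph")
    return SpanningTree(n_nodes=n, edges=tuple(edges))


def _component_sizes_without(tree: SpanningTree, v: int) -> list[int]:
    adj = tree.adjacency()
    seen = [False] * tree.n_nodes
    seen[v] = True
    sizes = []
    for start in adj[v]:
        if seen[start]:
            continue
        stack, size = [start], 0
        seen[start] = True
        while stack:
            node = stack.pop()
            size += 1
            for nb in adj[node]:
                if not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        sizes.append(size)
    return sizes


def betweenness(tree: SpanningTree, denominator: str = "pairs") -> CentralityVector:
    """Exact tree betweenness centrality via component counting."""
    if denominator not in ("pairs", "interior"):
        raise ValueError(f"unknown denominator convention {denominator!r}")
    n = tree.n_nodes
    counts = np.zeros(n, dtype=np.int64)
    for v in range(n):
        sizes = _component_sizes_without(tree, v)
        if sum(sizes) != n - 1:
            raise ValueError("tree is disconnected")
        counts[v] = comb(n - 1, 2) - sum(comb(m, 2) for m in sizes)
    denom = comb(n, 2) if denominator == "pairs" else comb(n - 1, 2)
    return CentralityVector(
        bc=counts / denom, denominator=denominator, raw_counts=counts
    )


def regional_bc(
    centrality: CentralityVector, montage: Montage
) -> dict[str, float]:
    """Mean betweenness centrality per region cluster plus global mean."""
    bc = centrality.bc
    if len(bc) != montage.n_channels:
        raise ValueError(
            f"centrality has {len(bc)} nodes, montage {montage.n_channels}"
        )
    out = {"global": float(bc.mean())}
    for region in REGION_NAMES:
        idx = montage.region_indices(region)
        out[region] = float(bc[idx].mean())
    return out
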