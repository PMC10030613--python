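"""Minimum spanning trees over cluster centers.

The tree topology over K cluster centers is the MST of the complete graph
whose edge weights are squared Euclidean distances between centers.  The
integer program (symmetric binary adjacency, K-1 edges, acyclic and
connected) relaxes to a problem solved exactly by Kruskal's algorithm;
the implementation uses a deterministic lexicographic tie-break so equal
runs give identical trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["TreeTopology", "pairwise_sq_distances", "kruskal_mst"]


@dataclass
class TreeTopology:
    """Spanning tree over K vertices as a symmetric binary adjacency."""

    B: np.ndarray
    edges: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B)
        K = self.n_vertices
        if self.B.shape != (K, K):
            raise ValueError("adjacency must be square")
        if not np.array_equal(self.B, self.B.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.B) != 0):
            raise ValueError("no self loops allowed")
        if int(self.B.sum()) != 2 * (K - 1):
            raise ValueError("a spanning tree on K vertices has K-1 edges")
        if not self.edges:
            iu, ju = np.nonzero(np.triu(self.B))
            self.edges = list(zip(iu.tolist(), ju.tolist()))
        if K > 1 and not _is_connected(self.edges, K):
            raise ValueError("edge set does not connect all vertices")

    @property
    def n_vertices(self) -> int:
        return self.B.shape[0]

    def degree(self) -> np.ndarray:
        return self.B.sum(axis=1).astype(int)


def _is_connected(edges: list[tuple[int, int]], K: int) -> bool:
    parent = list(range(K))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        parent[find(i)] = find(j)
    return len({find(v) for v in range(K)}) == 1


def pairwise_sq_distances(C: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between the rows of ``C``."""
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if not np.isfinite(C).all():
        raise ValueError("centers must be finite")
    W = cdist(C, C, "sqeuclidean")
    np.fill_diagonal(W, 0.0)
    return np.maximum(W, W.T)  # exact symmetry


def kruskal_mst(W: np.ndarray) -> TreeTopology:
    """Minimum spanning tree of a complete weighted graph by Kruskal.

    ``W`` must be a symmetric nonnegative matrix with zero diagonal.
    Equal-weight edges are taken in lexicographic order on
    ``(min(i,j), max(i,j))``, so the result is deterministic even when
    the MST is not unique.
    """
    W = np.asarray(W, dtype=float)
    K = W.shape[0]
    if W.shape != (K, K):
        raise ValueError("W must be square")
    if not np.allclose(W, W.T, rtol=0, atol=1e-12):
        raise ValueError("W must be symmetric")
    if (W < 0).any():
        raise ValueError("W must be nonnegative")

    iu, ju = np.triu_indices(K, k=1)
    order = np.lexsort((ju, iu, W[iu, ju]))  # weight, then (i, j)

    parent = list(range(K))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    B = np.zeros((K, K), dtype=int)
    edges: list[tuple[int, int]] = []
    for idx in order:
        i, j = int(iu[idx]), int(ju[idx])
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            B[i, j] = B[j, i] = 1
            edges.append((i, j))
            if len(edges) == K - 1:
                break
    return TreeTopology(B, edges)


def tree_weight(tree: TreeTopology, W: np.ndarray) -> float:
    """Total weight of the tree's edges under ``W``."""
    return float(sum(W[i, j] for i, j in tree.edges))
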