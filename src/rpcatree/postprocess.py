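"""From solver state to biological outputs.

Turns the soft assignment into hard cluster labels, merges duplicate
centers (a converged run typically parks many initial centers on the
same clone/state), rounds continuous centers to discrete genotype
states, roots the clone-level tree at the least-mutated clone, and
decomposes a cluster tree into branches for trajectory comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .mst import TreeTopology
from .rpca import DataKind
from .solver import SolverState, update_B

__all__ = [
    "ClusterModel",
    "CloneTree",
    "hard_assign",
    "dedup_centers",
    "round_genotypes",
    "root_clone_tree",
    "tree_branches",
    "summarize",
]


@dataclass
class ClusterModel:
    """Hard clustering after center deduplication.

    ``labels`` are 0-based cluster indices for every row; ``sizes`` sum
    to the number of rows (retained empty root candidates have size 0).
    """

    labels: np.ndarray
    centers: np.ndarray
    sizes: np.ndarray

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


@dataclass
class CloneTree:
    """Rooted clone-level tree with (for discrete data) clone genotypes."""

    topology: TreeTopology
    root: int
    clone_genotypes: np.ndarray | None = None
    oriented_edges: list[tuple[int, int]] = field(default_factory=list)  # parent -> child


def hard_assign(R: np.ndarray) -> np.ndarray:
    """Maximum-membership labels; ties go to the smallest cluster index."""
    R = np.asarray(R)
    if R.ndim != 2:
        raise ValueError("R must be 2-D")
    return R.argmax(axis=1)


def round_genotypes(values: np.ndarray, kind: DataKind | str, max_state: int | None = None) -> np.ndarray:
    """Round continuous recovered values to legal genotype states.

    SNV states live in {0, 1, 2}; copy-number states are nonnegative
    integers, clipped above at ``max_state`` when given.  Idempotent.
    """
    kind = DataKind(kind)
    if kind == DataKind.continuous:
        raise ValueError("rounding is defined for discrete kinds only")
    out = np.rint(np.asarray(values, dtype=float)).astype(int)
    if kind == DataKind.snv:
        return np.clip(out, 0, 2)
    upper = max_state if max_state is not None else None
    return np.clip(out, 0, upper)


def _merge_groups(C: np.ndarray, close) -> list[list[int]]:
    """Union-find grouping of center indices under a pairwise predicate matrix."""
    K = C.shape[0]
    parent = list(range(K))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(K):
        for j in range(i + 1, K):
            if close[i, j]:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for k in range(K):
        groups.setdefault(find(k), []).append(k)
    return sorted(groups.values(), key=lambda g: g[0])


def dedup_centers(
    C: np.ndarray,
    labels: np.ndarray,
    eps: float | None = None,
    kind: DataKind | str = DataKind.continuous,
    max_state: int | None = None,
    keep_empty_root: bool = True,
) -> ClusterModel:
    """Merge duplicate centers and drop empty clusters.

    For discrete kinds, centers are first rounded to genotype states and
    merged on exact equality; for continuous data, centers within
    ``eps`` (default ``1e-6 * sqrt(N)``) of each other are merged into
    their size-weighted mean.  Clusters left with zero cells are
    dropped, except that for discrete data an empty all-reference clone
    is retained (``keep_empty_root``) as the natural root candidate of
    the clone tree.
    """
    C = np.asarray(C, dtype=float)
    labels = np.asarray(labels)
    K, N = C.shape
    if eps is None:
        eps = 1e-6 * np.sqrt(N)
    if eps < 0:
        raise ValueError("eps must be nonnegative")
    kind = DataKind(kind)
    discrete = kind in (DataKind.snv, DataKind.cna)
    if discrete:
        G = round_genotypes(C, kind, max_state)
        close = squareform(pdist(G, "hamming") == 0) if K > 1 else np.zeros((1, 1), bool)
    else:
        G = C
        close = squareform(pdist(C) <= eps) if K > 1 else np.zeros((1, 1), bool)

    counts = np.bincount(labels, minlength=K).astype(float)
    groups = _merge_groups(C, close)

    new_centers, new_sizes, keep_groups = [], [], []
    for g in groups:
        size = counts[g].sum()
        if discrete:
            center = G[g[0]].astype(float)
        else:
            w = counts[g]
            center = (C[g] * w[:, None]).sum(axis=0) / w.sum() if w.sum() > 0 else C[g].mean(axis=0)
        is_reference = discrete and not np.any(G[g[0]] != (0 if kind == DataKind.snv else _modal_states(G)))
        if size == 0:
            if not (keep_empty_root and is_reference):
                continue
        new_centers.append(center)
        new_sizes.append(size)
        keep_groups.append(g)

    # at most one retained empty all-reference clone; dedup above guarantees it
    remap = np.full(K, -1, dtype=int)
    for new_k, g in enumerate(keep_groups):
        for old_k in g:
            remap[old_k] = new_k
    new_labels = remap[labels]
    if (new_labels < 0).any():  # cells of a dropped cluster cannot occur (size>0 kept)
        raise RuntimeError("internal error: dropped a non-empty cluster")
    return ClusterModel(new_labels, np.asarray(new_centers), np.asarray(new_sizes))


def _modal_states(G: np.ndarray) -> np.ndarray:
    """Per-column modal state — the copy-number 'reference' baseline."""
    out = np.empty(G.shape[1], dtype=int)
    for j in range(G.shape[1]):
        vals, cnt = np.unique(G[:, j], return_counts=True)
        out[j] = vals[cnt.argmax()]
    return out


def root_clone_tree(
    model: ClusterModel,
    topology: TreeTopology,
    kind: DataKind | str,
    max_state: int | None = None,
) -> CloneTree:
    """Root the clone tree at the least-mutated clone.

    The reference genotype is all-zero for SNV data and the per-column
    modal state for copy-number data; the root is the clone with the
    fewest non-reference entries (ties broken toward the smallest index,
    with a warning).  Edges are re-oriented away from the root.
    """
    kind = DataKind(kind)
    if kind == DataKind.continuous:
        raise ValueError("clone-tree rooting is defined for discrete kinds only")
    G = round_genotypes(model.centers, kind, max_state)
    if topology.n_vertices != G.shape[0]:
        raise ValueError("topology size does not match the number of clones")
    if kind == DataKind.snv:
        reference = np.zeros(G.shape[1], dtype=int)
    else:
        reference = _modal_states(G)
    burden = (G != reference).sum(axis=1)
    best = int(burden.argmin())
    if (burden == burden[best]).sum() > 1:
        warnings.warn("tie for least-mutated clone; rooting at the smallest index", stacklevel=2)
    oriented = _orient_from(topology, best)
    return CloneTree(topology, best, G, oriented)


def _orient_from(topology: TreeTopology, root: int) -> list[tuple[int, int]]:
    B = topology.B
    seen = {root}
    queue = [root]
    oriented: list[tuple[int, int]] = []
    while queue:
        u = queue.pop(0)
        for v in np.nonzero(B[u])[0]:
            v = int(v)
            if v not in seen:
                seen.add(v)
                oriented.append((u, v))
                queue.append(v)
    return oriented


def tree_branches(topology: TreeTopology) -> np.ndarray:
    """Branch id per vertex: components after cutting at junction vertices.

    Vertices of degree >= 3 (branch points) each get their own id; the
    remaining paths between them form the branches.  Used to compare a
    fitted cluster tree against true branch assignments of a trajectory.
    """
    K = topology.n_vertices
    deg = topology.degree()
    junction = deg >= 3
    branch = np.full(K, -1, dtype=int)
    next_id = 0
    for v in np.nonzero(junction)[0]:
        branch[v] = next_id
        next_id += 1
    for v in range(K):
        if branch[v] >= 0:
            continue
        stack = [v]
        branch[v] = next_id
        while stack:
            u = stack.pop()
            for w in np.nonzero(topology.B[u])[0]:
                w = int(w)
                if branch[w] == -1 and not junction[w]:
                    branch[w] = next_id
                    stack.append(w)
        next_id += 1
    return branch


def branch_assignments(
    topology: TreeTopology,
    centers: np.ndarray,
    threshold: float = 0.25,
) -> np.ndarray:
    """Branch id per vertex from the geometry of the cluster tree.

    A developmental branch moves through expression space in its own
    consistent direction (the genes it up-regulates), so tree edges are
    grouped into direction families by complete-linkage clustering of
    ``1 - |cos|`` between edge directions at the given threshold; each
    vertex takes the family of its longest incident edge (short edges
    near junctions carry mostly noise).  Unlike :func:`tree_branches`,
    this handles junctions that the spanning tree traverses as
    degree-2 chains.
    """
    edges = topology.edges
    K = topology.n_vertices
    if not edges:
        return np.zeros(K, dtype=int)
    D = np.array([centers[j] - centers[i] for i, j in edges], dtype=float)
    L = np.linalg.norm(D, axis=1)
    L = np.where(L > 1e-12, L, 1e-12)
    Du = D / L[:, None]
    if len(edges) == 1:
        fam = np.zeros(1, dtype=int)
    else:
        from sklearn.cluster import AgglomerativeClustering

        dist = np.clip(1.0 - np.abs(Du @ Du.T), 0.0, None)
        fam = AgglomerativeClustering(
            n_clusters=None, distance_threshold=threshold,
            metric="precomputed", linkage="complete",
        ).fit(dist).labels_
    incident: dict[int, list[int]] = {v: [] for v in range(K)}
    for e, (i, j) in enumerate(edges):
        incident[i].append(e)
        incident[j].append(e)
    out = np.zeros(K, dtype=int)
    for v in range(K):
        if incident[v]:
            out[v] = fam[max(incident[v], key=lambda e: L[e])]
    return out


def summarize(
    state: SolverState,
    kind: DataKind | str = DataKind.continuous,
    max_state: int | None = None,
    keep_empty_root: bool = True,
) -> tuple[ClusterModel, TreeTopology, CloneTree | None]:
    """Standard postprocessing chain for a fitted state.

    Hard-assigns cells, deduplicates centers, rebuilds the spanning tree
    over the final centers, and (for discrete data) roots the clone
    tree.  Returns ``(model, final_tree, clone_tree_or_None)``.
    """
    kind = DataKind(kind)
    labels = hard_assign(state.R)
    model = dedup_centers(
        state.C, labels, kind=kind, max_state=max_state, keep_empty_root=keep_empty_root
    )
    if model.n_clusters == 1:
        tree = TreeTopology(np.zeros((1, 1), dtype=int))
    else:
        if kind == DataKind.continuous:
            tree = update_B(model.centers)
        else:
            tree = update_B(round_genotypes(model.centers, kind, max_state).astype(float))
    clone_tree = None
    if kind != DataKind.continuous:
        clone_tree = root_clone_tree(model, tree, kind, max_state)
    return model, tree, clone_tree
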