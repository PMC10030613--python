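"""Synthetic data with known low-dimensional structure.

Three generator families cover the regimes the solver is built for:

* :func:`simulate_shape2d` — 2-D point clouds along named parametric
  structures (spiral, circle, three clusters, tree, distorted S, two
  moons) with a handful of sharp outliers far from the structure.
* :func:`simulate_scsnv` — discrete single-cell SNV genotype matrices:
  a random rooted clone tree, genotypes in {0, 1, 2} accumulating
  mutations along edges, observed under symmetric state-flip errors and
  dropout (missing entries).
* :func:`simulate_branching_expression` — continuous expression along a
  random branching trajectory: each branch up-regulates its own gene
  block on top of the inherited ancestral profile.

All generators are bit-reproducible under a fixed seed and return the
ground truth (clean matrix, labels, tree, outlier rows, mask) needed to
score recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mst import TreeTopology
from .rpca import DataKind, ObservedMatrix

__all__ = [
    "SimTruth",
    "simulate_shape2d",
    "simulate_scsnv",
    "simulate_branching_expression",
    "SHAPE2D_KINDS",
]

SHAPE2D_KINDS = ("spiral", "circle", "three_cluster", "tree", "s_shape", "two_moons")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated observation."""

    true_matrix: np.ndarray
    labels: np.ndarray | None = None
    tree: TreeTopology | None = None
    outlier_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    mask: np.ndarray | None = None
    branch_position: np.ndarray | None = None  # arc-length t in [0,1], trajectories only
    scale: float = 1.0  # characteristic spatial extent of the structure


def _random_rooted_tree(n: int, rng: np.random.Generator) -> tuple[TreeTopology, int, list[tuple[int, int]]]:
    """Uniform labeled tree via a random Pruefer sequence, rooted at vertex 0.

    Returns the topology, the root, and the edges oriented parent->child.
    """
    if n == 1:
        return TreeTopology(np.zeros((1, 1), dtype=int)), 0, []
    if n == 2:
        edges = [(0, 1)]
    else:
        seq = rng.integers(0, n, size=n - 2)
        degree = np.ones(n, dtype=int)
        for v in seq:
            degree[v] += 1
        edges = []
        ptr = list(seq)
        leaves = sorted(v for v in range(n) if degree[v] == 1)
        import heapq

        heapq.heapify(leaves)
        for v in ptr:
            leaf = heapq.heappop(leaves)
            edges.append((leaf, int(v)))
            degree[v] -= 1
            if degree[v] == 1:
                heapq.heappush(leaves, int(v))
        u, w = heapq.heappop(leaves), heapq.heappop(leaves)
        edges.append((u, w))
    B = np.zeros((n, n), dtype=int)
    for i, j in edges:
        B[i, j] = B[j, i] = 1
    topo = TreeTopology(B)
    # orient away from root 0 by BFS
    parent = {0: None}
    order = [0]
    seen = {0}
    queue = [0]
    while queue:
        u = queue.pop(0)
        for v in np.nonzero(B[u])[0]:
            v = int(v)
            if v not in seen:
                seen.add(v)
                parent[v] = u
                order.append(v)
                queue.append(v)
    oriented = [(parent[v], v) for v in order[1:]]
    return topo, 0, oriented


# ---------------------------------------------------------------------------
# 2-D shapes


def _shape_points(kind: str, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray | None]:
    t = rng.uniform(0, 1, size=n)
    if kind == "spiral":
        ang = t * 3 * np.pi
        r = 0.2 + t
        return np.column_stack([r * np.cos(ang), r * np.sin(ang)]), None
    if kind == "circle":
        ang = t * 2 * np.pi
        return np.column_stack([np.cos(ang), np.sin(ang)]), None
    if kind == "three_cluster":
        centers = np.array([[0.0, 0.0], [2.5, 0.0], [1.25, 2.2]])
        lab = rng.integers(0, 3, size=n)
        return centers[lab] + 0.15 * rng.standard_normal((n, 2)), lab
    if kind == "tree":
        # three segments: trunk plus two branches from its tip
        segs = np.array([[[0, 0], [0, 2]], [[0, 2], [-1.5, 3.5]], [[0, 2], [1.5, 3.5]]], dtype=float)
        lab = rng.integers(0, 3, size=n)
        a, b = segs[lab, 0], segs[lab, 1]
        return a + t[:, None] * (b - a), lab
    if kind == "s_shape":
        x = t * 4 - 2
        return np.column_stack([x, np.sin(1.5 * x) + 0.1 * x**2]), None
    if kind == "two_moons":
        lab = (rng.uniform(size=n) < 0.5).astype(int)
        ang = t * np.pi
        x = np.where(lab == 0, np.cos(ang), 1 - np.cos(ang))
        y = np.where(lab == 0, np.sin(ang), 0.5 - np.sin(ang))
        return np.column_stack([x, y]), lab
    raise ValueError(f"unknown 2-D shape kind {kind!r}; choose from {SHAPE2D_KINDS}")


def simulate_shape2d(
    kind: str,
    n: int,
    n_noise: int = 0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[ObservedMatrix, SimTruth]:
    """Sample ``n`` points along a named 2-D structure plus sharp outliers.

    Outliers (``n_noise`` of them, at most 10) are placed at least three
    times the structure's spatial scale away from every clean point and
    recorded in ``SimTruth.outlier_index``.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    if not 0 <= n_noise <= 10:
        raise ValueError("n_noise must be between 0 and 10")
    rng = np.random.default_rng(seed)
    clean, labels = _shape_points(kind, n, rng)
    pts = clean + noise_sd * rng.standard_normal(clean.shape)
    center = pts.mean(axis=0)
    scale = float(np.linalg.norm(pts - center, axis=1).max())
    outliers = []
    for _ in range(n_noise):
        ang = rng.uniform(0, 2 * np.pi)
        rad = scale * rng.uniform(4.0, 6.0)
        outliers.append(center + rad * np.array([np.cos(ang), np.sin(ang)]))
    X = np.vstack([pts] + [o[None, :] for o in outliers]) if outliers else pts
    out_idx = np.arange(n, n + len(outliers))
    if labels is not None:
        labels = np.concatenate([labels, np.full(len(outliers), -1)])
    truth = SimTruth(
        true_matrix=np.vstack([clean] + [o[None, :] for o in outliers]) if outliers else clean,
        labels=labels,
        outlier_index=out_idx,
        mask=np.ones(X.shape, dtype=bool),
        scale=scale,
    )
    return ObservedMatrix(X, None, DataKind.continuous), truth


# ---------------------------------------------------------------------------
# discrete clone genotypes


def simulate_scsnv(
    n_cells: int,
    n_sites: int,
    n_clones: int,
    clone_sizes: list[int] | None = None,
    error_rate: float = 0.30,
    dropout_rate: float = 0.20,
    seed: int = 0,
) -> tuple[ObservedMatrix, SimTruth]:
    """Single-cell SNV genotypes from a random clone tree under noise.

    A rooted clone tree is sampled uniformly (Pruefer); the root clone
    carries the all-reference genotype and each edge mutates a disjoint
    block of sites to a state in {1, 2} (heterozygous/homozygous),
    accumulated along the path from the root.  Each cell copies its
    clone's genotype; entries then drop out (missing) with probability
    ``dropout_rate`` and each remaining observed entry is flipped to one
    of the other two legal states (uniformly) with probability
    ``error_rate``.

    Defaults mirror a hard regime: 30% flip errors, 20% dropout.
    """
    if clone_sizes is None:
        base = n_cells // n_clones
        clone_sizes = [base] * n_clones
        clone_sizes[-1] += n_cells - base * n_clones
    clone_sizes = list(clone_sizes)
    if len(clone_sizes) != n_clones or sum(clone_sizes) != n_cells:
        raise ValueError("clone_sizes must have n_clones entries summing to n_cells")
    if not (0 <= error_rate < 1 and 0 <= dropout_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    tree, root, oriented = _random_rooted_tree(n_clones, rng)
    genotypes = np.zeros((n_clones, n_sites), dtype=int)
    n_edges = max(len(oriented), 1)
    block = n_sites // n_edges if oriented else n_sites
    site_perm = rng.permutation(n_sites)
    for e, (p, c) in enumerate(oriented):
        lo = e * block
        hi = (e + 1) * block if e < n_edges - 1 else n_sites
        sites = site_perm[lo:hi]
        genotypes[c] = genotypes[p]
        genotypes[c, sites] = rng.choice([1, 2], size=len(sites))

    labels = np.repeat(np.arange(n_clones), clone_sizes)
    truth_matrix = genotypes[labels]

    X = truth_matrix.astype(float).copy()
    flip = rng.uniform(size=X.shape) < error_rate
    if flip.any():
        # uniform flip to one of the two other legal states
        offset = rng.integers(1, 3, size=flip.sum())
        X[flip] = (X[flip] + offset) % 3
    mask = rng.uniform(size=X.shape) >= dropout_rate
    obs = ObservedMatrix(np.where(mask, X, 0.0), mask, DataKind.snv)
    truth = SimTruth(
        true_matrix=truth_matrix,
        labels=labels,
        tree=tree,
        mask=mask,
    )
    return obs, truth


# ---------------------------------------------------------------------------
# continuous branching expression


def simulate_branching_expression(
    n_branches: int,
    cells_per_branch: int,
    n_genes: int,
    genes_per_branch: int,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[ObservedMatrix, SimTruth]:
    """Expression along a random branching trajectory.

    Each branch owns a disjoint block of ``genes_per_branch`` genes;
    a cell at position ``t`` in [0, 1] along branch ``b`` expresses the
    fully up-regulated profile inherited from ancestral branches plus
    ``t`` times the up-regulation of branch ``b``'s own block, plus
    Gaussian noise.  Branch labels, positions and the branch tree are
    stored in the truth.
    """
    if n_branches * genes_per_branch > n_genes:
        raise ValueError("gene blocks exceed the number of genes")
    rng = np.random.default_rng(seed)
    tree, root, oriented = _random_rooted_tree(n_branches, rng)
    # ancestral full profiles: branch b fully expressed = parent profile + own block
    amplitude = 3.0
    own = np.zeros((n_branches, n_genes))
    perm = rng.permutation(n_genes)
    for b in range(n_branches):
        own[b, perm[b * genes_per_branch : (b + 1) * genes_per_branch]] = amplitude
    ancestral = np.zeros((n_branches, n_genes))
    # root's block ramps from zero; children start from parent's full profile
    order = [root] + [c for _, c in oriented]
    parent_of = {c: p for p, c in oriented}
    for b in order:
        if b == root:
            ancestral[b] = 0.0
        else:
            p = parent_of[b]
            ancestral[b] = ancestral[p] + own[p]

    M = n_branches * cells_per_branch
    labels = np.repeat(np.arange(n_branches), cells_per_branch)
    t = rng.uniform(0, 1, size=M)
    clean = ancestral[labels] + t[:, None] * own[labels]
    X = clean + noise_sd * rng.standard_normal(clean.shape)
    truth = SimTruth(
        true_matrix=clean,
        labels=labels,
        tree=tree,
        mask=np.ones(X.shape, dtype=bool),
        branch_position=t,
    )
    return ObservedMatrix(X, None, DataKind.continuous), truth
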