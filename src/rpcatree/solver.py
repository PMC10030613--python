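"""Joint low-rank recovery, soft clustering, and tree learning.

The optimizer minimizes, over ``{A, E, C, B, R}``,

    ||A||_*  +  lam * ||P_Phi(E)||_1
    + (theta/2) * sum_{k,k'} b_{k,k'} ||C_k - C_k'||^2
    + gamma * sum_{i,k} r_{i,k} ||A_i - C_k||^2
    + gamma * sigma * sum_{i,k} r_{i,k} log r_{i,k}
    subject to  A + E = X,  B a spanning tree,  R row-stochastic,

by ADMM over the two blocks {B, R} and {A, C, E}:

* ``B``: minimum spanning tree over centers (Kruskal, exact).
* ``R``: entropy-regularized softmax over negative squared distances
  (exact, closed form).
* ``E``: masked elementwise shrinkage (exact, closed form).
* ``A``: proximal-gradient step with singular value thresholding on the
  smooth part of the augmented Lagrangian.
* ``C``: closed-form linear solve against the tree Laplacian.

The constraint ``A + E = X`` is handled by an augmented Lagrange
multiplier ``Lambda`` with penalty ``mu`` grown geometrically.  In the
default *inexact* mode each outer iteration applies every block update
once; *exact* mode iterates the {E, A, C} subproblem to a tolerance
before touching the multiplier, matching the exact formulation.

The entropy temperature ``sigma`` interpolates between hard K-means-style
assignment (``sigma -> 0``) and uniform membership; the tree-smoothness
weight ``theta`` pulls centers that are adjacent on the current spanning
tree toward each other, which is what lets sharp outliers be expelled
into ``E`` instead of growing spurious branches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh, solve
from scipy.spatial.distance import cdist
from scipy.special import softmax, xlogy
from sklearn.cluster import KMeans

from .mst import TreeTopology, kruskal_mst, pairwise_sq_distances
from .rpca import (
    ConvergenceWarning,
    Decomposition,
    ObservedMatrix,
    _svt_with_values,
    soft_threshold,
    svt,
)

__all__ = [
    "Hyperparams",
    "SolverState",
    "select_hyperparams",
    "build_laplacian",
    "update_C",
    "update_E",
    "update_A",
    "update_R",
    "update_B",
    "fit",
    "objective",
    "augmented_objective",
]


@dataclass
class Hyperparams:
    """Trade-off weights and solver controls.

    lam
        Sparse-error weight on ``||P_Phi(E)||_1``.
    theta
        Tree-smoothness weight on squared center-to-center edge lengths.
    gamma
        Clustering weight pulling recovered rows toward their centers.
    sigma
        Entropy temperature of the soft assignment (units: squared
        data distance); smaller is harder.
    K
        Initial number of cluster centers (final count after
        deduplication is usually smaller).
    mu, rho
        Augmented-Lagrange penalty (``None`` = ``1.25/||X||_2`` at fit
        time) and its geometric growth factor.
    warmup_tol, max_warmup
        Stopping rule of the decomposition warm-up phase (the pure
        low-rank + sparse ALM run before the clustering and tree terms
        are switched on).
    """

    lam: float
    theta: float
    gamma: float
    sigma: float
    K: int
    mu: float | None = None
    rho: float = 1.5
    outer_tol: float = 1e-7
    inner_tol: float = 1e-6
    feas_tol: float = 1e-6
    max_outer: int = 200
    max_inner: int = 50
    warmup_tol: float = 1e-9
    max_warmup: int = 500
    mu_hold: int | None = None
    adapt_sigma: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lam", "theta", "gamma", "sigma", "rho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mu is not None and self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.K < 1:
            raise ValueError("K must be at least 1")


@dataclass
class SolverState:
    """Everything the joint optimizer produced."""

    decomposition: Decomposition
    C: np.ndarray
    R: np.ndarray
    B: TreeTopology
    hyper: Hyperparams
    objective_trace: list[float] = field(default_factory=list)
    residuals: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    @property
    def A(self) -> np.ndarray:
        return self.decomposition.A

    @property
    def E(self) -> np.ndarray:
        return self.decomposition.E


def default_K(M: int) -> int:
    """Initial center count: every row its own center for small data,
    then 1 center per 5 rows up to 1000 rows, 1 per 50 beyond."""
    if M <= 500:
        return M
    if M <= 1000:
        return int(np.ceil(M / 5))
    return int(np.ceil(M / 50))


def select_hyperparams(obs: ObservedMatrix, seed: int = 0, **overrides) -> Hyperparams:
    """Adaptive trade-off weights from the data dimensions and noise scale.

    ``lam = 1/sqrt(max(M,N))`` is the standard robust-PCA scaling of the
    sparse-error weight; ``theta = gamma = sqrt(MN)/N`` balances the
    tree and clustering terms against the nuclear norm; ``sigma =
    var(X) * N / sqrt(max(M,N))`` (sample variance over observed
    entries) sets the assignment temperature at the scale of squared
    row-to-center distances, soft enough for duplicate centers of one
    state to merge yet far below between-state separations.  Any field
    can be overridden by keyword.
    """
    M, N = obs.shape
    if M < 2:
        raise ValueError("need at least 2 rows")
    lam = 1.0 / np.sqrt(max(M, N))
    theta = gamma = np.sqrt(M * N) / N
    observed = obs.X[obs.mask]
    var = float(observed.var(ddof=1)) if observed.size > 1 else 0.0
    if var <= 0:
        warnings.warn("observed entries have zero variance; flooring sigma", stacklevel=2)
        var = 1e-8
    sigma = max(var * N / np.sqrt(max(M, N)), 1e-8)
    params = dict(
        lam=lam,
        theta=theta,
        gamma=gamma,
        sigma=sigma,
        K=default_K(M),
        seed=seed,
        # the variance-based temperature belongs to the low-rank + sparse
        # regime; let fit() recalibrate it from center spacing when the
        # decomposition model is rejected, unless the user pinned sigma
        adapt_sigma="sigma" not in overrides,
    )
    params.update(overrides)
    return Hyperparams(**params)


def _spacing_sigma(C: np.ndarray) -> float:
    """Median nearest-neighbor squared distance between centers.

    The assignment temperature used when the data has no usable
    low-rank + sparse decomposition: soft at the scale of the local
    center spacing, hard beyond it.
    """
    if C.shape[0] < 2:
        return 1e-8
    D = cdist(C, C, "sqeuclidean")
    np.fill_diagonal(D, np.inf)
    nn = D.min(axis=1)
    nn = nn[np.isfinite(nn)]
    return max(float(np.median(nn)), 1e-8)


def build_laplacian(B: TreeTopology | np.ndarray) -> np.ndarray:
    """Graph Laplacian ``L = diag(B 1) - B`` of a tree adjacency."""
    Bm = B.B if isinstance(B, TreeTopology) else np.asarray(B)
    Bm = Bm.astype(float)
    return np.diag(Bm.sum(axis=1)) - Bm


def _coupling_matrix(R: np.ndarray, B: TreeTopology, theta: float, gamma: float) -> np.ndarray:
    """``(theta/gamma) L + Gamma`` — the SPD system shared by C and S."""
    L = build_laplacian(B)
    return (theta / gamma) * L + np.diag(R.sum(axis=0))


def _inv_sqrt_psd(H: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    """Symmetric inverse square root with an eigenvalue floor."""
    w, V = eigh(H)
    w = np.maximum(w, floor)
    return (V / np.sqrt(w)) @ V.T


def update_C(
    A: np.ndarray,
    R: np.ndarray,
    B: TreeTopology,
    theta: float,
    gamma: float,
) -> np.ndarray:
    """Closed-form center update ``C = ((theta/gamma)L + Gamma)^{-1} R^T A``."""
    H = _coupling_matrix(R, B, theta, gamma)
    rhs = R.T @ A
    try:
        C = solve(H, rhs, assume_a="sym")
        if not np.isfinite(C).all():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular center system; adding 1e-10 ridge", stacklevel=2)
        C = solve(H + 1e-10 * np.eye(H.shape[0]), rhs, assume_a="sym")
    return C


def update_E(
    X: np.ndarray,
    A: np.ndarray,
    Lam: np.ndarray,
    mu: float,
    lam: float,
    mask: np.ndarray,
) -> np.ndarray:
    """Sparse-error update: shrink observed residuals, carry unobserved ones.

    Observed entries get ``S_{lam/mu}(X - A + Lambda/mu)``; unobserved
    entries are set to ``X - A + Lambda/mu`` — the exact minimizer of
    the augmented Lagrangian there (no l1 weight applies off-mask) — so
    the equality constraint is driven to zero and the imputed value
    lives in ``A``.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    T = X - A + Lam / mu
    return np.where(mask, soft_threshold(T, lam / mu), T)


def _lipschitz(S: np.ndarray, mu: float, gamma: float) -> float:
    """Spectral norm of ``(mu+2*gamma)I - 2*gamma*S S^T`` via the K x K Gram."""
    M, K = S.shape
    nu = np.linalg.eigvalsh(S.T @ S)
    nu = np.clip(nu, 0.0, None)
    cand = np.abs(mu + 2 * gamma - 2 * gamma * nu)
    Lf = float(cand.max())
    if M > K:  # S S^T has a null space, contributing eigenvalue mu+2*gamma
        Lf = max(Lf, mu + 2 * gamma)
    return Lf


def update_A(
    A: np.ndarray,
    X: np.ndarray,
    E: np.ndarray,
    S: np.ndarray,
    Lam: np.ndarray,
    mu: float,
    gamma: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One proximal-gradient step on the smooth part of the A-subproblem.

    The smooth part ``f(A) = -<Lambda, A> + mu/2 ||X-A-E||_F^2 +
    gamma(||A||_F^2 - ||S^T A||_F^2)`` has Lipschitz gradient with
    constant ``L_f = ||(mu+2*gamma)I - 2*gamma*S S^T||``; the step is
    followed by singular value thresholding at ``1/L_f`` (the prox of
    the nuclear norm).  Returns the new ``A`` and its singular values.
    """
    Lf = _lipschitz(S, mu, gamma)
    grad = -Lam + mu * (A - (X - E)) + 2 * gamma * (A - S @ (S.T @ A))
    if not np.isfinite(grad).all():
        raise FloatingPointError("non-finite gradient in A update")
    G = A - grad / Lf
    return _svt_with_values(G, 1.0 / Lf)


def update_R(A: np.ndarray, C: np.ndarray, sigma: float) -> np.ndarray:
    """Soft assignment ``r_{i,k} ∝ exp(-||A_i - C_k||^2 / sigma)``.

    Computed with a row-wise stable softmax so no row underflows to
    all-zeros even at very small temperatures.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    D = cdist(A, np.atleast_2d(C), "sqeuclidean")
    return softmax(-D / sigma, axis=1)


def update_B(C: np.ndarray) -> TreeTopology:
    """Spanning tree over centers: Kruskal on squared Euclidean distances."""
    return kruskal_mst(pairwise_sq_distances(C))


def _entropy(R: np.ndarray) -> float:
    return float(xlogy(R, R).sum())


def objective(
    X: np.ndarray,
    mask: np.ndarray,
    A: np.ndarray,
    E: np.ndarray,
    C: np.ndarray,
    R: np.ndarray,
    B: TreeTopology,
    hyper: Hyperparams,
    nuclear: float | None = None,
) -> float:
    """The joint objective (constraint terms excluded)."""
    if nuclear is None:
        nuclear = float(np.linalg.norm(A, "nuc"))
    sparse = hyper.lam * float(np.abs(E[mask]).sum())
    L = build_laplacian(B)
    tree = hyper.theta * float(np.einsum("kn,kl,ln->", C, L, C))
    D = cdist(A, np.atleast_2d(C), "sqeuclidean")
    cluster = hyper.gamma * float((R * D).sum())
    entropy = hyper.gamma * hyper.sigma * _entropy(R)
    return nuclear + sparse + tree + cluster + entropy


def augmented_objective(
    X: np.ndarray,
    mask: np.ndarray,
    A: np.ndarray,
    E: np.ndarray,
    C: np.ndarray,
    R: np.ndarray,
    B: TreeTopology,
    hyper: Hyperparams,
    Lam: np.ndarray,
    mu: float,
) -> float:
    """Augmented Lagrangian: objective plus multiplier and penalty terms."""
    res = X - A - E
    return (
        objective(X, mask, A, E, C, R, B, hyper)
        + float((Lam * res).sum())
        + 0.5 * mu * float(np.linalg.norm(res) ** 2)
    )


def _init_centers(A: np.ndarray, K: int, seed: int) -> np.ndarray:
    """K-means (k-means++ seeded Lloyd) centers on the rows of A.

    Full Lloyd iterations spread centers by variance, so long segments
    of a trajectory get several centers instead of one; deterministic
    under the seed.
    """
    M = A.shape[0]
    if K >= M:
        return A.copy()
    try:
        km = KMeans(n_clusters=K, n_init=1, random_state=seed).fit(A)
        return np.asarray(km.cluster_centers_, dtype=float)
    except Exception:  # degenerate data (e.g. massive duplication)
        rng = np.random.default_rng(seed)
        idx = rng.choice(M, size=K, replace=False)
        return A[idx].copy()


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.isfinite(arr).all():
        raise FloatingPointError(f"non-finite values produced by the {name} update")


def fit(
    obs: ObservedMatrix | np.ndarray,
    hyper: Hyperparams | None = None,
    mode: str = "inexact",
) -> SolverState:
    """Run the joint optimizer on an observed matrix.

    Parameters
    ----------
    obs
        Observed data (plain arrays are wrapped as fully observed,
        continuous).
    hyper
        Hyper-parameters; ``None`` selects them adaptively via
        :func:`select_hyperparams`.
    mode
        ``"inexact"`` (default; one pass of every block update per outer
        iteration) or ``"exact"`` (the {E, A, C} subproblem is iterated
        to ``inner_tol`` before the multiplier moves).

    Returns
    -------
    SolverState
        Final decomposition, centers, soft assignment, tree, and the
        per-iteration objective trace.

    Notes
    -----
    The optimization runs in two phases.  A *decomposition warm-up*
    first solves the pure low-rank + sparse subproblem (the objective
    with the clustering and tree terms inactive) by the standard
    inexact ALM from ``A = 0`` — this is what gives the aggressive
    early singular-value thresholding that strips gross errors before
    any center exists to mislead the clustering.  The *coupled phase*
    then starts from the warm iterate: centers by k-means++ seeding on
    the denoised rows, a fresh multiplier ramp, and one pass of every
    block update per outer iteration (``inexact``) or block updates
    iterated to ``inner_tol`` (``exact``).  Convergence requires both a
    relative objective change below ``outer_tol`` and a constraint
    residual ``||X-A-E||_F/||X||_F`` below ``feas_tol``.
    """
    if mode not in ("inexact", "exact"):
        raise ValueError(f"unknown mode {mode!r}")
    if not isinstance(obs, ObservedMatrix):
        obs = ObservedMatrix(np.asarray(obs, dtype=float), None)
    if hyper is None:
        hyper = select_hyperparams(obs)
    X, mask = obs.X, obs.mask
    M, N = X.shape
    if hyper.K > M:
        raise ValueError(f"K={hyper.K} exceeds the number of rows {M}")

    norm_X = np.linalg.norm(X)
    if norm_X == 0:
        raise ValueError("input matrix is identically zero")
    mu0 = hyper.mu if hyper.mu is not None else 1.25 / np.linalg.norm(X, 2)
    mu_max = 1e7 * mu0

    # --- phase 1: decomposition warm-up (clustering and tree inactive) ---
    A = np.zeros_like(X)
    E = np.zeros_like(X)
    Lam = np.zeros_like(X)
    mu = mu0
    for _ in range(hyper.max_warmup):
        E = update_E(X, A, Lam, mu, hyper.lam, mask)
        A = svt(X - E + Lam / mu, 1.0 / mu)
        res_mat = X - A - E
        Lam = Lam + mu * res_mat
        mu = min(hyper.rho * mu, mu_max)
        if np.linalg.norm(res_mat) / norm_X < hyper.warmup_tol:
            break
    _check_finite("warm-up", A)
    # Accept the warm start only when the low-rank + sparse model actually
    # explains the data: the error component must be sparse (otherwise the
    # structure itself was pushed into E, as happens for 2-D point clouds)
    # and the recovered signal genuinely low-rank (otherwise the nuclear
    # shrinkage has folded weak signal directions onto strong ones, as
    # happens under dense Gaussian noise).  A rejected warm-up means the
    # coupled phase starts from the zero-filled data and does the
    # structure learning itself.
    # What the decomposition produced decides the regime.  The warm start
    # is trusted only when it found a genuinely low-dimensional signal
    # (small effective rank) with the errors confined to a minority of
    # entries; otherwise the nuclear shrinkage has distorted weak signal
    # directions and the coupled phase restarts from the data.  When E
    # holds essentially all of the data the matrix is not low-rank at
    # all (a point cloud whose geometry IS the signal) and the coupled
    # phase must learn the structure itself.
    scale = max(float(np.std(X[mask])), 1e-300)
    active = np.abs(E[mask]) > 0.05 * scale
    frac_active = float(active.mean())
    geometry_regime = frac_active > 0.7  # E holds the data, not errors
    svals_A = np.linalg.svd(A, compute_uv=False)
    eff_rank = int((svals_A > 0.01 * max(svals_A[0], 1e-300)).sum())
    med_mag = (
        float(np.median(np.abs(E[mask][active]))) / scale if active.any() else np.inf
    )
    warm_accepted = (
        not geometry_regime
        and eff_rank <= 0.25 * min(M, N)  # a genuinely low-dimensional signal
        and med_mag >= 0.5  # errors are gross flips, not measurement noise
    )
    if not warm_accepted:
        A = X.copy()

    # --- phase 2: coupled clustering + tree refinement ---
    C = _init_centers(A, hyper.K, hyper.seed)
    sigma = hyper.sigma
    if not warm_accepted and hyper.adapt_sigma:
        # the variance-based temperature presumes denoised near-duplicate
        # rows; without the warm start, calibrate to the local center
        # spacing (a quarter of it when the data was merely not low-rank
        # enough, so adjacent trajectory segments stay distinct)
        spacing = _spacing_sigma(C)
        sigma = spacing if geometry_regime else spacing / 4.0
    hold = hyper.mu_hold
    if hold is None:
        # in the point-cloud regime the coupled phase is the structure
        # learner: the penalty stays low while the tree term walks sharp
        # outliers back to their tree-adjacent centers (a slow chain
        # diffusion), then ramps
        hold = 150 if geometry_regime else 0
    import dataclasses

    hyper = dataclasses.replace(hyper, sigma=sigma, mu_hold=hold)
    E = np.zeros_like(X)
    Lam = np.zeros_like(X)
    mu = mu0
    B = update_B(C)
    R = update_R(A, C, sigma)

    trace: list[float] = []
    residuals: list[float] = []
    converged = False
    it = 0
    for it in range(1, hyper.max_outer + hold + 1):  # hold extends the budget
        # --- {B, R} block ---
        B = update_B(C)
        R = update_R(A, C, hyper.sigma)
        _check_finite("R", R)
        # --- {E, A, C} block ---
        H = _coupling_matrix(R, B, hyper.theta, hyper.gamma)
        S = R @ _inv_sqrt_psd(H)
        if mode == "inexact":
            E = update_E(X, A, Lam, mu, hyper.lam, mask)
            _check_finite("E", E)
            A, svals = update_A(A, X, E, S, Lam, mu, hyper.gamma)
            _check_finite("A", A)
            C = update_C(A, R, B, hyper.theta, hyper.gamma)
            _check_finite("C", C)
        else:
            # solve the jointly convex {E, A, C} subproblem to feasibility
            # with a dedicated multiplier ramp; the outer trace is then
            # monotone by exact block minimization
            mu_in, Lam_in = mu0, np.zeros_like(X)
            for _ in range(hyper.max_warmup):
                E = update_E(X, A, Lam_in, mu_in, hyper.lam, mask)
                for _ in range(hyper.max_inner):
                    A_new, svals = update_A(A, X, E, S, Lam_in, mu_in, hyper.gamma)
                    step = np.linalg.norm(A_new - A) / max(1.0, np.linalg.norm(A))
                    A = A_new
                    if step < hyper.inner_tol:
                        break
                C = update_C(A, R, B, hyper.theta, hyper.gamma)
                res_in = X - A - E
                Lam_in = Lam_in + mu_in * res_in
                mu_in = min(hyper.rho * mu_in, mu_max)
                if np.linalg.norm(res_in) / norm_X < hyper.feas_tol:
                    break
            _check_finite("E", E)
            _check_finite("A", A)
            _check_finite("C", C)
        # --- multiplier / penalty (inexact mode only; exact mode keeps
        # its subproblem multipliers internal) ---
        res_mat = X - A - E
        if mode == "inexact":
            Lam = Lam + mu * res_mat
            if it > hold:
                mu = min(hyper.rho * mu, mu_max)
        res = float(np.linalg.norm(res_mat) / norm_X)
        residuals.append(res)

        obj = objective(X, mask, A, E, C, R, B, hyper, nuclear=float(svals.sum()))
        if not np.isfinite(obj):
            raise FloatingPointError("objective became non-finite")
        trace.append(obj)
        if len(trace) >= 2:
            rel = abs(trace[-2] - obj) / max(1.0, abs(trace[-2]))
            if rel < hyper.outer_tol and res < hyper.feas_tol:
                converged = True
                break

    if not converged:
        warnings.warn(
            f"joint solver stopped at max_outer={hyper.max_outer} "
            f"(last residual {residuals[-1]:.3g}); trace attached to state",
            ConvergenceWarning,
            stacklevel=2,
        )
    decomp = Decomposition(A, E, it, residuals[-1])
    return SolverState(decomp, C, R, B, hyper, trace, residuals, converged, it)
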