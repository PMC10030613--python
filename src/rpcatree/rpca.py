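"""Robust PCA with missing-entry support.

Decomposes an observed matrix ``X`` into a low-rank signal ``A`` plus a
sparse error ``E`` by minimizing ``||A||_* + lam * ||P_Phi(E)||_1`` subject
to ``A + E = X``, where ``P_Phi`` projects onto the observed entries.  When
every entry is observed this is the classical convex relaxation of robust
PCA; with missing entries it simultaneously performs matrix completion
(the imputed values are read from ``A``).  The solver is an inexact
augmented-Lagrange-multiplier (ALM) method.

This module also provides the two scalar/spectral proximal kernels shared
with the joint solver: elementwise soft thresholding (prox of the l1 norm)
and singular value thresholding (prox of the nuclear norm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "DataKind",
    "ObservedMatrix",
    "Decomposition",
    "ConvergenceWarning",
    "soft_threshold",
    "svt",
    "rpca_decompose",
]


class DataKind(str, Enum):
    """What the matrix entries mean; drives rounding and rooting downstream."""

    continuous = "continuous"
    snv = "snv"
    cna = "cna"


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when an iterative solver stops at max_iter."""


@dataclass
class ObservedMatrix:
    """A data matrix with an observed-entry mask.

    Rows are data points (cells), columns are features (genes, mutation
    sites, copy-number bins).  ``X`` holds 0 at unobserved positions (the
    "zero-fill" convention); ``mask`` is True where the entry was observed.
    """

    X: np.ndarray
    mask: np.ndarray
    kind: DataKind = DataKind.continuous
    row_names: list[str] | None = None
    col_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if self.mask is None:
            self.mask = np.ones(self.X.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.X.shape:
            raise ValueError("mask shape must match X")
        M, N = self.X.shape
        if M < 2 or N < 1:
            raise ValueError("need at least 2 rows and 1 column")
        if not np.isfinite(self.X[self.mask]).all():
            raise ValueError("X must be finite at observed positions")
        if isinstance(self.kind, str):
            self.kind = DataKind(self.kind)
        # zero-fill: value at unobserved positions is irrelevant downstream
        self.X = np.where(self.mask, self.X, 0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    @property
    def missing_rate(self) -> float:
        """Fraction s of unobserved entries, in [0, 1]."""
        return 1.0 - self.mask.mean()


@dataclass
class Decomposition:
    """Low-rank/sparse split ``A + E = X`` (within the solver tolerance).

    On unobserved entries the recovered data value is read from ``A``;
    ``E`` there holds the residual bookkeeping term, not signal.
    """

    A: np.ndarray
    E: np.ndarray
    n_iter: int = 0
    residual: float = field(default=np.nan)

    @property
    def recovered(self) -> np.ndarray:
        return self.A


def soft_threshold(x, tau: float):
    """Elementwise shrinkage ``sign(x) * max(|x| - tau, 0)``.

    The proximal operator of ``tau * |.|``; scalar in, scalar out, array
    in, array out.
    """
    if tau < 0:
        raise ValueError(f"threshold must be nonnegative, got {tau}")
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.maximum(np.abs(x) - tau, 0.0)
    return out if out.ndim else float(out)


def svt(G: np.ndarray, tau: float) -> np.ndarray:
    """Singular value thresholding: prox of ``tau * ||.||_*``.

    Soft-thresholds the singular values of ``G`` at ``tau`` and
    reassembles; never increases the nuclear norm.
    """
    if tau < 0:
        raise ValueError(f"threshold must be nonnegative, got {tau}")
    G = np.asarray(G, dtype=float)
    if not np.isfinite(G).all():
        raise ValueError("svt requires finite entries")
    U, s, Vt = np.linalg.svd(G, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    return (U * s) @ Vt


def _svt_with_values(G: np.ndarray, tau: float) -> tuple[np.ndarray, np.ndarray]:
    U, s, Vt = np.linalg.svd(G, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    return (U * s) @ Vt, s


def default_lam(obs: ObservedMatrix) -> float:
    """Sparsity weight ``(1 + 3s) / sqrt(max(M, N))`` with missing rate s."""
    M, N = obs.shape
    return (1.0 + 3.0 * obs.missing_rate) / np.sqrt(max(M, N))


def rpca_decompose(
    obs: ObservedMatrix | np.ndarray,
    lam: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 500,
    refine_iter: int = 5000,
    refine_tol: float = 1e-12,
) -> Decomposition:
    """Split ``obs`` into low-rank ``A`` plus sparse ``E`` by inexact ALM.

    Parameters
    ----------
    obs
        Observed matrix (a plain array is treated as fully observed,
        continuous).
    lam
        Sparsity trade-off; defaults to ``(1+3s)/sqrt(max(M,N))``.
    tol
        Stop when ``||X-A-E||_F / ||X||_F < tol``.
    max_iter
        Iteration cap of the penalty-ramp phase; hitting it emits
        :class:`ConvergenceWarning` and continues with the last iterate.
    refine_iter, refine_tol
        After the ramp reaches feasibility, plain two-block ADMM at a
        fixed moderate penalty polishes the iterate to the optimum of
        the convex program, stopping when the relative objective change
        over 50 iterations falls below ``refine_tol`` (set
        ``refine_iter=0`` to skip).  The fast ramp alone can stall
        slightly above the optimum on small ill-conditioned instances.

    Notes
    -----
    ALM internals: multiplier update ``Lambda += mu*(X-A-E)``; penalty
    ``mu_0 = 1.25/||X||_2`` grown by 1.5x per iteration, capped at
    ``1e7*mu_0``.  Observed entries of ``E`` are soft-thresholded at
    ``lam/mu``; unobserved entries carry the exact residual so the
    constraint holds there and the imputation lives in ``A``.
    """
    if not isinstance(obs, ObservedMatrix):
        obs = ObservedMatrix(np.asarray(obs, dtype=float), None)
    X, mask = obs.X, obs.mask
    if not mask.any():
        raise ValueError("need at least one observed entry")
    if lam is None:
        lam = default_lam(obs)
    if lam <= 0:
        raise ValueError(f"lam must be positive, got {lam}")

    norm_X = np.linalg.norm(X)
    if norm_X == 0:
        return Decomposition(np.zeros_like(X), np.zeros_like(X), 0, 0.0)
    mu0 = 1.25 / np.linalg.norm(X, 2)
    mu, rho, mu_max = mu0, 1.5, 1e7 * mu0
    A = np.zeros_like(X)
    E = np.zeros_like(X)
    Lam = np.zeros_like(X)

    res = np.inf
    for it in range(1, max_iter + 1):
        # E-step: masked shrinkage; exact residual off-mask (no l1 weight there)
        T = X - A + Lam / mu
        E = np.where(mask, soft_threshold(T, lam / mu), T)
        # A-step: nuclear prox of the penalty-quadratic minimizer
        A = svt(X - E + Lam / mu, 1.0 / mu)
        R = X - A - E
        Lam = Lam + mu * R
        mu = min(rho * mu, mu_max)
        res = np.linalg.norm(R) / norm_X
        if res < tol:
            break
    else:
        warnings.warn(
            f"RPCA did not reach tol={tol:g} in {max_iter} iterations "
            f"(residual {res:.3g}); returning last iterate",
            ConvergenceWarning,
            stacklevel=2,
        )

    # refinement: fixed-penalty ADMM converges to the convex optimum
    if refine_iter > 0:
        mu = 10.0 * mu0
        prev_obj = np.inf
        for k in range(1, refine_iter + 1):
            T = X - A + Lam / mu
            E = np.where(mask, soft_threshold(T, lam / mu), T)
            A = svt(X - E + Lam / mu, 1.0 / mu)
            Lam = Lam + mu * (X - A - E)
            if k % 50 == 0:
                obj = np.linalg.norm(A, "nuc") + lam * np.abs(E[mask]).sum()
                if abs(prev_obj - obj) < refine_tol * max(1.0, abs(obj)):
                    break
                prev_obj = obj
        res = float(np.linalg.norm(X - A - E) / norm_X)
    return Decomposition(A, E, it, float(res))


def rpca_objective(decomp: Decomposition, mask: np.ndarray, lam: float) -> float:
    """Objective ``||A||_* + lam*||P_Phi(E)||_1`` at the decomposition."""
    nuc = np.linalg.norm(decomp.A, "nuc")
    return float(nuc + lam * np.abs(decomp.E[mask]).sum())
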