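"""Low-rank representation (LRR) denoising.

Solves, per modality, the convex program

    min_{X,E}  ||X||_*  +  lambda * ||E||_{2,1}    s.t.  A = A X + E

where ``||X||_*`` is the nuclear norm (sum of singular values) and
``||E||_{2,1}`` the sum of column Euclidean norms, so E is driven to be
column-sparse: whole corrupted samples land in E while ``A X`` recovers the
self-expressive low-rank part. The solver is the standard inexact augmented
Lagrange multiplier (ALM) scheme with the auxiliary split ``J = X``:

    J   <- svt(X + Y2/mu, 1/mu)                       (nuclear-norm prox)
    X   <- (I + A^T A)^{-1} (A^T (A - E + Y1/mu) + J - Y2/mu)
    E   <- l21_shrink(A - A X + Y1/mu, lambda/mu)     (L2,1 prox)
    Y1  <- Y1 + mu (A - A X - E);  Y2 <- Y2 + mu (X - J);  mu <- min(rho mu, mu_max)

On noiseless rank-r input the minimiser of the E-free program is the
shape-interaction matrix ``V_r V_r^T`` of the skinny SVD — used as the test
oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .datasets import MultimodalDataset

__all__ = [
    "SolverSettings",
    "LRRSolution",
    "svt",
    "l21_shrink",
    "lrr_solve",
    "default_lambda",
    "denoise_modalities",
]

logger = logging.getLogger(__name__)


class NumericalError(RuntimeError):
    """Raised when a numerical routine cannot produce a usable result."""


@dataclass
class SolverSettings:
    """Inexact-ALM controls: stopping tolerance (relative constraint
    residual), iteration cap, initial penalty ``mu0``, growth ``rho`` and
    penalty ceiling ``mu_max``."""

    tol: float = 1e-6
    max_iter: int = 500
    mu0: float = 1e-2
    rho: float = 1.1
    mu_max: float = 1e6

    def validate(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.rho <= 1:
            raise ValueError("rho must be > 1")
        if self.mu0 <= 0:
            raise ValueError("mu0 must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class LRRSolution:
    X: np.ndarray  # n x n coefficient matrix
    E: np.ndarray  # d x n column-sparse error
    denoised: np.ndarray  # A @ X
    lam: float
    residuals: list[float] = field(default_factory=list)  # ||A - AX - E||_F per iter
    objectives: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


def svt(m: np.ndarray, tau: float) -> np.ndarray:
    """Singular-value thresholding: proximal operator of the nuclear norm.

    Returns ``U diag(max(sigma - tau, 0)) V^T``.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    u, s, vt = np.linalg.svd(np.asarray(m, dtype=float), full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    return (u * s) @ vt


def l21_shrink(m: np.ndarray, tau: float) -> np.ndarray:
    """Column-wise shrinkage: proximal operator of the L2,1 norm.

    Column j is scaled by ``max(0, 1 - tau/||col_j||)``; columns with norm
    <= tau vanish.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    m = np.asarray(m, dtype=float)
    norms = np.linalg.norm(m, axis=0)
    scale = np.zeros_like(norms)
    nz = norms > tau
    scale[nz] = 1.0 - tau / norms[nz]
    return m * scale


def default_lambda(shape: tuple[int, int]) -> float:
    """Robust-PCA-style heuristic 1/sqrt(max(d, n))."""
    return 1.0 / np.sqrt(max(shape))


def lrr_solve(
    a: np.ndarray,
    lam: float | None = None,
    settings: SolverSettings | None = None,
) -> LRRSolution:
    """Solve ``min ||X||_* + lam ||E||_{2,1} s.t. A = A X + E`` by inexact ALM.

    Parameters
    ----------
    a:
        Fully observed d x n data matrix (run completion first).
    lam:
        Positive balance parameter; defaults to ``1/sqrt(max(d, n))``.
    settings:
        Solver controls; see :class:`SolverSettings`.

    Returns
    -------
    LRRSolution with coefficient matrix X, error matrix E, the denoised
    reconstruction ``A @ X``, and the per-iteration convergence trace. If the
    iteration cap is hit the last iterate is returned with
    ``converged=False`` and a logged warning.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[1] < 2:
        raise ValueError("A must be a d x n matrix with n >= 2")
    if not np.isfinite(a).all():
        raise ValueError("A must be finite with no missing entries")
    if lam is None:
        lam = default_lambda(a.shape)
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    settings = settings or SolverSettings()
    settings.validate()

    d, n = a.shape
    a_norm = max(1.0, np.linalg.norm(a))
    ata = a.T @ a
    factor = cho_factor(np.eye(n) + ata, lower=True)

    x = np.zeros((n, n))
    j = np.zeros((n, n))
    e = np.zeros((d, n))
    y1 = np.zeros((d, n))
    y2 = np.zeros((n, n))
    mu = settings.mu0

    residuals: list[float] = []
    objectives: list[float] = []
    converged = False
    it = 0
    for it in range(1, settings.max_iter + 1):
        j = svt(x + y2 / mu, 1.0 / mu)
        x = cho_solve(factor, a.T @ (a - e + y1 / mu) + j - y2 / mu)
        e = l21_shrink(a - a @ x + y1 / mu, lam / mu)

        primal = a - a @ x - e
        split = x - j
        y1 += mu * primal
        y2 += mu * split
        mu = min(settings.rho * mu, settings.mu_max)

        res = np.linalg.norm(primal)
        residuals.append(res)
        objectives.append(
            float(np.linalg.svd(x, compute_uv=False).sum())
            + lam * float(np.linalg.norm(x=e, axis=0).sum())
        )
        if max(res, np.linalg.norm(split)) / a_norm < settings.tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "lrr_solve: iteration cap %d reached (relative residual %.2e)",
            settings.max_iter,
            residuals[-1] / a_norm,
        )
    return LRRSolution(
        X=x,
        E=e,
        denoised=a @ x,
        lam=lam,
        residuals=residuals,
        objectives=objectives,
        converged=converged,
        n_iter=it,
    )


def detect_corrupted_columns(
    a: np.ndarray,
    frac: float = 0.1,
    lambda_grid: list[float] | None = None,
    settings: SolverSettings | None = None,
) -> tuple[np.ndarray, LRRSolution, float]:
    """Flag grossly corrupted sample columns via the L2,1 error term.

    Because A itself is the self-expression dictionary, a large-norm corrupted
    column can absorb itself into ``A X`` when lambda is large; corruption
    surfaces in E only for sufficiently small lambda. The balance parameter is
    therefore selected on a small grid (multiples of the ``1/sqrt(max(d,n))``
    heuristic) by an unsupervised criterion: maximise the gap between the mean
    E column norm of the top-``frac`` columns and that of the remainder. Only
    the expected corruption rate ``frac`` enters the selection, never the true
    corruption indices.

    Returns (indices of the top-``frac`` columns by E norm, the winning
    solution, the selected lambda).
    """
    a = np.asarray(a, dtype=float)
    base = default_lambda(a.shape)
    if lambda_grid is None:
        lambda_grid = [base * f for f in (0.1, 0.25, 0.5, 1.0, 2.0)]
    n = a.shape[1]
    k = max(1, int(round(frac * n)))
    best = None
    for lam in lambda_grid:
        sol = lrr_solve(a, lam=lam, settings=settings)
        norms = np.sort(np.linalg.norm(sol.E, axis=0))[::-1]
        gap = norms[:k].mean() / (norms[k:].mean() + 1e-12)
        if best is None or gap > best[0]:
            best = (gap, sol, lam)
    _, sol, lam = best
    idx = np.argsort(np.linalg.norm(sol.E, axis=0))[::-1][:k]
    return np.sort(idx), sol, lam


def shape_interaction_matrix(a: np.ndarray, rank: int) -> np.ndarray:
    """Closed-form noiseless LRR minimiser ``V_r V_r^T`` from the skinny SVD."""
    _, _, vt = np.linalg.svd(np.asarray(a, dtype=float), full_matrices=False)
    vr = vt[:rank].T
    return vr @ vr.T


def denoise_modalities(
    dataset: MultimodalDataset,
    lambdas: float | list[float] | None = None,
    settings: SolverSettings | None = None,
) -> tuple[MultimodalDataset, list[LRRSolution]]:
    """Replace each modality by its LRR reconstruction ``A @ X``.

    ``lambdas`` may be a scalar (shared), a per-modality list, or None for
    the per-modality default heuristic. The dataset must be fully imputed.
    Solutions (with traces) are returned alongside for inspection.
    """
    k = len(dataset.modalities)
    if lambdas is None:
        lam_list: list[float | None] = [None] * k
    elif np.isscalar(lambdas):
        lam_list = [float(lambdas)] * k
    else:
        lam_list = list(lambdas)
        if len(lam_list) != k:
            raise ValueError("lambdas length must match number of modalities")

    out = dataset.copy()
    solutions: list[LRRSolution] = []
    for mod, lam in zip(out.modalities, lam_list):
        if mod.missing_mask.any() or np.isnan(mod.values).any():
            raise ValueError(f"modality {mod.name!r} has missing entries; impute first")
        try:
            sol = lrr_solve(mod.values, lam=lam, settings=settings)
        except Exception as exc:  # noqa: BLE001 - annotate modality then re-raise
            raise NumericalError(f"LRR failed on modality {mod.name!r}: {exc}") from exc
        mod.values = sol.denoised
        solutions.append(sol)
    return out, solutions
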