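"""Missing-value completion for modality matrices.

Three completers are provided:

* ``knn_impute`` — inverse-distance-weighted K-nearest-neighbour averaging,
  the completer used by the main fusion pipeline. Each missing entry is
  replaced by the weighted mean of the K nearest samples' observed values at
  that feature, with weights ``w_i = (1/d_i) / sum_j (1/d_j)``.
* ``em_impute`` — iterated Gaussian conditional-mean imputation under a
  multivariate-normal model (the "EM" baseline, default 50 iterations).
* ``svd_impute`` — iterative low-rank completion: alternately fill missing
  entries and truncate the SVD to the smallest rank retaining a target
  fraction of squared-singular-value energy (default 95%).

Distances for KNN are Euclidean over co-observed coordinates, rescaled by
``sqrt(d / n_co_observed)`` so that sparsely co-observed pairs are not
artificially close. A neighbour at distance zero is an exact match and wins
outright (the inverse-distance weight degenerates there).

All completers leave observed entries bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datasets import ModalityMatrix

__all__ = ["ImputationResult", "knn_impute", "em_impute", "svd_impute", "mean_impute"]

logger = logging.getLogger(__name__)


@dataclass
class ImputationResult:
    completed: np.ndarray  # d x n, no NaN
    method: str
    params: dict = field(default_factory=dict)
    converged: bool | None = None

    def as_modality(self, template: ModalityMatrix) -> ModalityMatrix:
        return ModalityMatrix(
            values=self.completed.copy(),
            missing_mask=np.zeros_like(self.completed, dtype=bool),
            name=template.name,
            feature_names=list(template.feature_names),
            sample_ids=list(template.sample_ids),
        )


def _values_and_mask(m: ModalityMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(m, ModalityMatrix):
        vals = np.asarray(m.values, dtype=float)
        mask = np.asarray(m.missing_mask, dtype=bool) | np.isnan(vals)
        return vals, mask
    vals = np.asarray(m, dtype=float)
    return vals, np.isnan(vals)


def _feature_means(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Row (feature) means over observed entries; 0 for fully missing rows."""
    obs = ~mask
    counts = obs.sum(axis=1)
    sums = np.where(obs, values, 0.0).sum(axis=1)
    means = np.zeros(values.shape[0])
    nz = counts > 0
    means[nz] = sums[nz] / counts[nz]
    return means


def mean_impute(m: ModalityMatrix | np.ndarray) -> ImputationResult:
    """Feature-mean fill; the reference floor other completers must beat."""
    values, mask = _values_and_mask(m)
    completed = values.copy()
    means = _feature_means(values, mask)
    rows, cols = np.nonzero(mask)
    completed[rows, cols] = means[rows]
    return ImputationResult(completed, "mean", {})


def _scaled_distances(
    target: np.ndarray,
    ref_values: np.ndarray,
    ref_mask: np.ndarray,
    metric: str = "euclidean",
) -> np.ndarray:
    """Distance from one sample column to every reference column over
    co-observed coordinates, rescaled by d / n_co (inside the root for
    euclidean) so sparsely co-observed pairs are not artificially close.
    inf when no coordinate is co-observed."""
    d = target.shape[0]
    t_obs = ~np.isnan(target)
    co = t_obs[:, None] & ~ref_mask  # d x n_ref
    diff = np.where(co, (target[:, None] - np.where(ref_mask, 0.0, ref_values)), 0.0)
    n_co = co.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        if metric == "euclidean":
            dist = np.sqrt((diff**2).sum(axis=0) * (d / n_co))
        elif metric == "manhattan":
            dist = np.abs(diff).sum(axis=0) * (d / n_co)
        else:
            raise ValueError(f"unknown distance metric {metric!r}")
    dist[n_co == 0] = np.inf
    return dist


def knn_impute(
    m: ModalityMatrix | np.ndarray,
    k: int = 5,
    reference: ModalityMatrix | np.ndarray | None = None,
    distance: str = "euclidean",
) -> ImputationResult:
    """K-nearest-neighbour completion with inverse-distance weights.

    Parameters
    ----------
    m:
        Modality matrix (d x n, columns-as-samples) with NaN / mask missing
        entries.
    k:
        Neighbour count (>= 1). If fewer than ``k`` usable donors exist for a
        cell, all available donors are used and a warning is logged.
    reference:
        Optional donor pool (e.g. the completed training fold when imputing
        held-out samples). Defaults to ``m`` itself, excluding the column
        being imputed.
    distance:
        "euclidean" (default) or "manhattan", over co-observed coordinates.

    Notes
    -----
    Donors for cell (i, j) are reference columns with feature ``i`` observed
    and at least one co-observed coordinate with column ``j``. Exact matches
    (distance 0) are averaged and win outright. A cell with no usable donor
    falls back to the donor pool's feature mean, with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values, mask = _values_and_mask(m)
    d, n = values.shape
    self_reference = reference is None
    if self_reference:
        ref_values, ref_mask = values, mask
    else:
        ref_values, ref_mask = _values_and_mask(reference)
        if ref_values.shape[0] != d:
            raise ValueError("reference feature count must match input")

    completed = values.copy()
    ref_means = _feature_means(ref_values, ref_mask)
    work = np.where(mask, np.nan, values)
    short_cells = 0
    fallback_cells = 0

    for j in np.nonzero(mask.any(axis=0))[0]:
        dist = _scaled_distances(work[:, j], ref_values, ref_mask, distance)
        if self_reference:
            dist[j] = np.inf
        for i in np.nonzero(mask[:, j])[0]:
            usable = np.nonzero(~ref_mask[i] & np.isfinite(dist))[0]
            if usable.size == 0:
                completed[i, j] = ref_means[i]
                fallback_cells += 1
                continue
            if usable.size < k:
                short_cells += 1
            order = usable[np.argsort(dist[usable], kind="stable")[:k]]
            dk = dist[order]
            if np.any(dk == 0.0):
                completed[i, j] = ref_values[i, order[dk == 0.0]].mean()
            else:
                w = 1.0 / dk
                completed[i, j] = float(w @ ref_values[i, order] / w.sum())
    if short_cells:
        logger.warning(
            "knn_impute: %d cells had fewer than k=%d usable donors; used all available",
            short_cells,
            k,
        )
    if fallback_cells:
        logger.warning(
            "knn_impute: %d cells had no usable donor; fell back to feature means",
            fallback_cells,
        )
    return ImputationResult(completed, "knn", {"k": k, "distance": distance})


@dataclass
class GaussianModel:
    """Mean and covariance fitted on a completed training matrix, used to
    conditionally impute held-out columns without refitting."""

    mean: np.ndarray
    cov: np.ndarray

    def impute_columns(self, values: np.ndarray, mask: np.ndarray) -> np.ndarray:
        completed = values.copy()
        for j in np.nonzero(mask.any(axis=0))[0]:
            miss = mask[:, j]
            obs = ~miss
            if not obs.any():
                completed[miss, j] = self.mean[miss]
                continue
            s_oo = self.cov[np.ix_(obs, obs)]
            s_mo = self.cov[np.ix_(miss, obs)]
            resid = values[obs, j] - self.mean[obs]
            completed[miss, j] = self.mean[miss] + s_mo @ np.linalg.solve(s_oo, resid)
        return completed


def em_impute(
    m: ModalityMatrix | np.ndarray,
    n_iter: int = 50,
    tol: float = 1e-8,
    ridge_scale: float = 1e-6,
) -> ImputationResult:
    """Iterated Gaussian conditional-mean imputation.

    Fits a multivariate normal over features (samples as observations),
    replaces each sample's missing block by its conditional mean given the
    observed block, and iterates up to ``n_iter`` times (default 50) or until
    the largest imputed-entry change drops below ``tol``. The covariance is
    ridge-regularised by ``ridge_scale * trace(S)/d`` to guard singularity.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    values, mask = _values_and_mask(m)
    d, _ = values.shape
    if not mask.any():
        return ImputationResult(values.copy(), "em", {"n_iter": n_iter}, converged=True)

    x = mean_impute(m).completed
    converged = False
    model = None
    for _ in range(n_iter):
        mu = x.mean(axis=1)
        cov = np.cov(x, ddof=1) if d > 1 else np.atleast_2d(np.var(x, ddof=1))
        cov = np.atleast_2d(cov)
        ridge = ridge_scale * np.trace(cov) / d
        if ridge <= 0 or not np.isfinite(ridge):
            ridge = ridge_scale
        cov = cov + ridge * np.eye(d)
        model = GaussianModel(mu, cov)
        new_x = model.impute_columns(np.where(mask, x, values), mask)
        delta = np.max(np.abs(new_x[mask] - x[mask])) if mask.any() else 0.0
        x = new_x
        if delta < tol:
            converged = True
            break
    completed = values.copy()
    completed[mask] = x[mask]
    res = ImputationResult(completed, "em", {"n_iter": n_iter, "tol": tol}, converged)
    res.model = model  # fitted Gaussian, reusable for held-out columns
    return res


def _energy_rank(s: np.ndarray, energy: float) -> int:
    """Smallest k with cumulative squared singular values >= energy."""
    total = float((s**2).sum())
    if total == 0.0:
        return 0
    cum = np.cumsum(s**2) / total
    return int(np.searchsorted(cum, energy - 1e-12) + 1)


def svd_impute(
    m: ModalityMatrix | np.ndarray,
    energy: float = 0.95,
    max_iter: int = 100,
    tol: float = 1e-7,
) -> ImputationResult:
    """Iterative SVD completion retaining an energy fraction of the spectrum.

    Alternates (a) filling missing entries with current estimates, (b)
    truncating the SVD to the smallest rank whose cumulative squared singular
    values reach ``energy``, (c) refreshing the missing entries from the
    truncation, until the relative change of imputed entries drops below
    ``tol`` or ``max_iter`` is hit (last iterate returned with a warning).
    """
    if not 0.0 < energy <= 1.0:
        raise ValueError("energy must lie in (0, 1]")
    values, mask = _values_and_mask(m)
    if not mask.any():
        return ImputationResult(values.copy(), "svd", {"energy": energy}, converged=True)

    x = mean_impute(m).completed
    converged = False
    rank = 0
    basis = None
    for _ in range(max_iter):
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        rank = _energy_rank(s, energy)
        low = (u[:, :rank] * s[:rank]) @ vt[:rank]
        basis = u[:, :rank]
        change = np.linalg.norm(low[mask] - x[mask])
        scale = max(1.0, np.linalg.norm(x[mask]))
        x = x.copy()
        x[mask] = low[mask]
        if change / scale < tol:
            converged = True
            break
    if not converged:
        logger.warning("svd_impute: no convergence within max_iter=%d", max_iter)
    completed = values.copy()
    completed[mask] = x[mask]
    res = ImputationResult(
        completed, "svd", {"energy": energy, "rank": rank}, converged
    )
    res.basis = basis  # training low-rank basis, reusable for held-out columns
    return res


def project_onto_basis(
    basis: np.ndarray, values: np.ndarray, mask: np.ndarray, means: np.ndarray
) -> np.ndarray:
    """Complete held-out columns by least-squares regression on a low-rank
    basis fitted elsewhere (missing entries predicted from observed ones)."""
    completed = values.copy()
    for j in np.nonzero(mask.any(axis=0))[0]:
        miss = mask[:, j]
        obs = ~miss
        if not obs.any() or basis.shape[1] == 0:
            completed[miss, j] = means[miss]
            continue
        coef, *_ = np.linalg.lstsq(basis[obs], values[obs, j], rcond=None)
        completed[miss, j] = basis[miss] @ coef
    return completed
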