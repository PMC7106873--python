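"""Discriminant correlation analysis (DCA) fusion, with the CCA baseline.

DCA fuses two feature sets A (p x n) and B (q x n) sharing labels:

1. Build each set's between-class scatter ``S_inter = Phi Phi^T`` with
   ``Phi = [sqrt(m_1)(a_bar_1 - a_bar), ..., sqrt(m_c)(a_bar_c - a_bar)]``
   (class-mean deviations weighted by class size).
2. Unitize: find ``W_inter`` (p x r) with ``W_inter^T S_inter W_inter = I_r``
   via the eigendecomposition of the small c x c matrix ``Phi^T Phi``.
3. Diagonalise the transformed between-class cross-covariance
   ``S'_ab = Phi'_a Phi'_b^T`` by SVD ``U S V^T`` and set
   ``W_ca = U S^{-1/2}``, ``W_cb = V S^{-1/2}``, so that
   ``W_ca^T S'_ab W_cb = I_r``.
4. Project ``A* = W_a A`` with ``W_a = W_ca^T W_inter_a^T`` (likewise B*),
   then fuse by series concatenation (row stacking) or summation.

The fused dimension per pair is at most ``2 (c - 1)``; three or more sets are
fused by a left-fold cascade. Because every ingredient is built from
class-mean deviations, adding a constant vector to all samples of a set
leaves the transform unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DCATransform",
    "FusedMatrix",
    "between_class_scatter",
    "unitize_scatter",
    "dca_fit",
    "dca_transform",
    "fuse_pair",
    "MultisetDCA",
    "fuse_multimodal",
    "CCAFuser",
    "cca_fuse",
]


@dataclass
class DCATransform:
    """Fitted pairwise DCA projection.

    ``W_a`` (r x p) and ``W_b`` (r x q) map each set into the common
    r-dimensional discriminant-correlated space, r <= n_classes - 1.
    """

    W_a: np.ndarray
    W_b: np.ndarray
    r: int
    eigvals_a: np.ndarray
    eigvals_b: np.ndarray
    cross_singvals: np.ndarray
    class_means_a: np.ndarray
    class_means_b: np.ndarray
    grand_mean_a: np.ndarray
    grand_mean_b: np.ndarray
    classes: np.ndarray


@dataclass
class FusedMatrix:
    """Fused feature block (rows = fused features, columns = samples) plus a
    provenance record of sources and per-stage dimensions."""

    values: np.ndarray
    provenance: list[dict] = field(default_factory=list)


def between_class_scatter(
    a: np.ndarray, labels: np.ndarray, weighted: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Between-class scatter of a (p x n) feature set.

    Returns ``(Phi, S_inter)`` where ``Phi`` is p x c with column j equal to
    ``sqrt(m_j) (mean_j - grand_mean)`` (or unweighted deviations when
    ``weighted=False``) and ``S_inter = Phi Phi^T``.
    """
    a = np.asarray(a, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("between-class scatter requires >= 2 classes")
    grand = a.mean(axis=1)
    cols = []
    for cls, m in zip(classes, counts):
        dev = a[:, labels == cls].mean(axis=1) - grand
        cols.append((np.sqrt(m) if weighted else 1.0) * dev)
    phi = np.column_stack(cols)
    return phi, phi @ phi.T


def unitize_scatter(
    phi: np.ndarray, energy_tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Whitening transform of the between-class scatter.

    Works in the small c x c space: with ``Phi^T Phi = Q L Q^T`` and
    eigenpairs above ``energy_tol * max(L)`` retained, ``W = Phi Q L^{-1}``
    satisfies ``W^T (Phi Phi^T) W = I_r``. Returns ``(W, kept eigenvalues)``.
    """
    phi = np.asarray(phi, dtype=float)
    gram = phi.T @ phi
    lam, q = np.linalg.eigh(gram)
    order = np.argsort(lam)[::-1]
    lam, q = lam[order], q[:, order]
    keep = lam > max(energy_tol * lam[0], 0.0)
    if lam[0] <= 0 or not keep.any():
        raise ValueError("no discriminative directions: between-class scatter is zero")
    lam, q = lam[keep], q[:, keep]
    w = phi @ q / lam  # Phi Q L^{-1}
    return w, lam


def _fix_svd_signs(u: np.ndarray, vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic SVD signs: largest-|entry| of each U column positive;
    the paired V row flips with it so U S V^T is unchanged."""
    for k in range(u.shape[1]):
        idx = np.argmax(np.abs(u[:, k]))
        if u[idx, k] < 0:
            u[:, k] = -u[:, k]
            vt[k, :] = -vt[k, :]
    return u, vt


def dca_fit(
    a: np.ndarray,
    b: np.ndarray,
    labels: np.ndarray,
    energy_tol: float = 1e-8,
    weighted: bool = True,
) -> DCATransform:
    """Fit the pairwise DCA transform on column-aligned sets A and B."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    labels = np.asarray(labels)
    if a.shape[1] != b.shape[1] or a.shape[1] != labels.shape[0]:
        raise ValueError("A, B and labels must be column-aligned on samples")

    phi_a, _ = between_class_scatter(a, labels, weighted=weighted)
    phi_b, _ = between_class_scatter(b, labels, weighted=weighted)
    w_ia, eig_a = unitize_scatter(phi_a, energy_tol)
    w_ib, eig_b = unitize_scatter(phi_b, energy_tol)

    phi_a_t = w_ia.T @ phi_a  # r_a x c, satisfies Phi' Phi'^T = I
    phi_b_t = w_ib.T @ phi_b
    s_ab = phi_a_t @ phi_b_t.T  # transformed between-class cross-covariance
    u, s, vt = np.linalg.svd(s_ab)
    if s.size == 0 or s[0] <= 0:
        raise ValueError("feature sets share no between-class correlation")
    r = int(np.sum(s > energy_tol * s[0]))
    u, vt = _fix_svd_signs(u[:, :r].copy(), vt[:r].copy())
    s = s[:r]
    inv_sqrt = 1.0 / np.sqrt(s)
    w_ca = u * inv_sqrt  # U S^{-1/2}
    w_cb = vt.T * inv_sqrt  # V S^{-1/2}

    classes = np.unique(labels)
    means_a = np.column_stack([a[:, labels == c].mean(axis=1) for c in classes])
    means_b = np.column_stack([b[:, labels == c].mean(axis=1) for c in classes])
    return DCATransform(
        W_a=w_ca.T @ w_ia.T,
        W_b=w_cb.T @ w_ib.T,
        r=r,
        eigvals_a=eig_a,
        eigvals_b=eig_b,
        cross_singvals=s,
        class_means_a=means_a,
        class_means_b=means_b,
        grand_mean_a=a.mean(axis=1),
        grand_mean_b=b.mean(axis=1),
        classes=classes,
    )


def dca_transform(
    t: DCATransform, a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a fitted transform: ``A* = W_a A``, ``B* = W_b B``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[0] != t.W_a.shape[1]:
        raise ValueError(
            f"A has {a.shape[0]} features, transform expects {t.W_a.shape[1]}"
        )
    if b.shape[0] != t.W_b.shape[1]:
        raise ValueError(
            f"B has {b.shape[0]} features, transform expects {t.W_b.shape[1]}"
        )
    return t.W_a @ a, t.W_b @ b


def fuse_pair(astar: np.ndarray, bstar: np.ndarray, mode: str = "concat") -> FusedMatrix:
    """Fuse two transformed sets by series concatenation (default) or sum."""
    astar = np.asarray(astar, dtype=float)
    bstar = np.asarray(bstar, dtype=float)
    if astar.shape[1] != bstar.shape[1]:
        raise ValueError(
            f"column mismatch: {astar.shape[1]} vs {bstar.shape[1]} samples"
        )
    if mode == "concat":
        values = np.vstack([astar, bstar])
    elif mode == "sum":
        if astar.shape != bstar.shape:
            raise ValueError("sum mode requires equal shapes")
        values = astar + bstar
    else:
        raise ValueError(f"unknown fusion mode {mode!r}")
    return FusedMatrix(values=values, provenance=[{"mode": mode, "rows": values.shape[0]}])


class MultisetDCA:
    """Left-fold cascade of pairwise DCA over two or more feature sets.

    ``fit`` learns one :class:`DCATransform` per stage on training data;
    ``transform`` applies the chain to new column-aligned sets, so held-out
    samples are projected without refitting.
    """

    def __init__(self, energy_tol: float = 1e-8, mode: str = "concat", weighted: bool = True):
        self.energy_tol = energy_tol
        self.mode = mode
        self.weighted = weighted
        self.stages: list[DCATransform] = []
        self.provenance: list[dict] = []

    def fit(self, matrices: list[np.ndarray], labels: np.ndarray) -> "MultisetDCA":
        if len(matrices) < 2:
            raise ValueError("need at least two feature sets to fuse")
        self.stages = []
        self.provenance = []
        acc = np.asarray(matrices[0], dtype=float)
        for i, mat in enumerate(matrices[1:], start=1):
            t = dca_fit(acc, mat, labels, self.energy_tol, weighted=self.weighted)
            astar, bstar = dca_transform(t, acc, mat)
            acc = fuse_pair(astar, bstar, self.mode).values
            self.stages.append(t)
            self.provenance.append({"stage": i, "r": t.r, "rows": acc.shape[0]})
        return self

    def transform(self, matrices: list[np.ndarray]) -> FusedMatrix:
        if not self.stages:
            raise RuntimeError("fit before transform")
        acc = np.asarray(matrices[0], dtype=float)
        for t, mat in zip(self.stages, matrices[1:]):
            astar, bstar = dca_transform(t, acc, np.asarray(mat, dtype=float))
            acc = fuse_pair(astar, bstar, self.mode).values
        return FusedMatrix(values=acc, provenance=list(self.provenance))


def fuse_multimodal(
    matrices: list[np.ndarray],
    labels: np.ndarray,
    energy_tol: float = 1e-8,
    mode: str = "concat",
) -> FusedMatrix:
    """Fit-and-transform convenience wrapper around :class:`MultisetDCA`."""
    return MultisetDCA(energy_tol=energy_tol, mode=mode).fit(matrices, labels).transform(
        matrices
    )


class CCAFuser:
    """Classical canonical correlation analysis fusion (baseline).

    Solves the whitened cross-covariance SVD with ridge-regularised within-set
    covariances (needed when p or q approaches or exceeds n), projects both
    centred sets onto the canonical directions and concatenates in series.
    More than two sets are fused by the same left-fold cascade as DCA.
    """

    def __init__(self, n_components: int | None = None, ridge: float = 1e-6):
        self.n_components = n_components
        self.ridge = ridge
        self.stages: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
        self.correlations_: list[np.ndarray] = []

    @staticmethod
    def _inv_sqrt(cov: np.ndarray, ridge: float) -> np.ndarray:
        lam, q = np.linalg.eigh(cov)
        lam = lam + ridge
        if lam.min() <= 0 or lam.max() / lam.min() > 1e12:
            raise ValueError(
                "within-set covariance is ill-conditioned; increase ridge > 0"
            )
        return (q / np.sqrt(lam)) @ q.T

    def _fit_pair(
        self, a: np.ndarray, b: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        n = a.shape[1]
        mu_a = a.mean(axis=1, keepdims=True)
        mu_b = b.mean(axis=1, keepdims=True)
        ac, bc = a - mu_a, b - mu_b
        caa = ac @ ac.T / (n - 1)
        cbb = bc @ bc.T / (n - 1)
        cab = ac @ bc.T / (n - 1)
        wa = self._inv_sqrt(caa, self.ridge)
        wb = self._inv_sqrt(cbb, self.ridge)
        u, s, vt = np.linalg.svd(wa @ cab @ wb)
        k = min(a.shape[0], b.shape[0], n - 1)
        if self.n_components is not None:
            k = min(k, self.n_components)
        u, vt = _fix_svd_signs(u[:, :k].copy(), vt[:k].copy())
        corr = np.clip(s[:k], 0.0, 1.0)
        return (wa @ u).T, (wb @ vt.T).T, mu_a, mu_b, corr

    def fit(self, matrices: list[np.ndarray], labels: np.ndarray | None = None) -> "CCAFuser":
        if len(matrices) < 2:
            raise ValueError("need at least two feature sets to fuse")
        self.stages = []
        self.correlations_ = []
        acc = np.asarray(matrices[0], dtype=float)
        for mat in matrices[1:]:
            mat = np.asarray(mat, dtype=float)
            pa, pb, mu_a, mu_b, corr = self._fit_pair(acc, mat)
            self.stages.append((pa, pb, mu_a, mu_b))
            self.correlations_.append(corr)
            acc = np.vstack([pa @ (acc - mu_a), pb @ (mat - mu_b)])
        return self

    def transform(self, matrices: list[np.ndarray]) -> FusedMatrix:
        if not self.stages:
            raise RuntimeError("fit before transform")
        acc = np.asarray(matrices[0], dtype=float)
        for (pa, pb, mu_a, mu_b), mat in zip(self.stages, matrices[1:]):
            mat = np.asarray(mat, dtype=float)
            acc = np.vstack([pa @ (acc - mu_a), pb @ (mat - mu_b)])
        prov = [
            {"stage": i + 1, "r": len(c), "first_corr": float(c[0]) if len(c) else 0.0}
            for i, c in enumerate(self.correlations_)
        ]
        return FusedMatrix(values=acc, provenance=prov)


def cca_fuse(
    a: np.ndarray,
    b: np.ndarray,
    n_components: int | None = None,
    ridge: float = 1e-6,
) -> tuple[FusedMatrix, np.ndarray]:
    """Pairwise CCA fusion; returns the fused matrix and canonical correlations
    (sorted non-increasing, in [0, 1])."""
    fuser = CCAFuser(n_components=n_components, ridge=ridge).fit([a, b])
    fused = fuser.transform([a, b])
    return fused, fuser.correlations_[0]
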