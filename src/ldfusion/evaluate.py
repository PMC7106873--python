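"""Classification evaluation under repeated stratified k-fold CV.

The protocol mirrors the common multimodal-diagnosis setup: an SVM (linear
kernel, C=1, features standardised per training fold) classifies fused
features under stratified 10-fold cross-validation repeated 10 times, and
six confusion metrics are reported as mean +/- SD over all folds: ACC, SEN,
SPE, BAC, PPV, NPV, plus a pooled ROC curve and its AUC.

Every fitted stage — imputer statistics, LRR denoising, DCA/CCA transforms,
standardisation, the SVM — is fit on training folds only and applied to the
held-out fold, so no test information leaks into preprocessing. A "leaky"
variant (global preprocessing before splitting) is available, clearly
labelled, for studying the size of that bias.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datasets import ModalityMatrix, MultimodalDataset
from .dca import CCAFuser, MultisetDCA
from .impute import (
    GaussianModel,
    em_impute,
    knn_impute,
    mean_impute,
    project_onto_basis,
    svd_impute,
    _feature_means,
    _values_and_mask,
)
from .lowrank import SolverSettings, lrr_solve

__all__ = [
    "ConfusionMetrics",
    "CVResult",
    "FusionPipeline",
    "confusion_metrics",
    "roc_auc",
    "repeated_cv",
    "compare_methods",
    "METHOD_REGISTRY",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("ACC", "SEN", "SPE", "BAC", "PPV", "NPV")


@dataclass
class ConfusionMetrics:
    """Binary-classification confusion counts and the six derived rates.

    Zero-denominator rates are NaN and listed in ``undefined`` — never
    silently coerced to 0.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    ACC: float = float("nan")
    SEN: float = float("nan")
    SPE: float = float("nan")
    BAC: float = float("nan")
    PPV: float = float("nan")
    NPV: float = float("nan")
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def confusion_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, positive_label
) -> ConfusionMetrics:
    """Compute ACC/SEN/SPE/BAC/PPV/NPV from binary predictions."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    if classes.size > 2:
        raise ValueError(
            "confusion_metrics handles binary tasks only; set up pairwise "
            "tasks (e.g. AD/NC, MCI/NC, AD/MCI) and evaluate each"
        )
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    tp = int(np.sum(pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    undefined: list[str] = []
    sen = _ratio(tp, tp + fn, "SEN", undefined)
    spe = _ratio(tn, tn + fp, "SPE", undefined)
    m = ConfusionMetrics(
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        ACC=_ratio(tp + tn, tp + tn + fp + fn, "ACC", undefined),
        SEN=sen,
        SPE=spe,
        BAC=(sen + spe) / 2.0,
        PPV=_ratio(tp, tp + fp, "PPV", undefined),
        NPV=_ratio(tn, tn + fn, "NPV", undefined),
    )
    if np.isnan(m.BAC):
        undefined.append("BAC")
    m.undefined = undefined
    return m


def roc_auc(
    scores: np.ndarray, labels: np.ndarray, positive_label
) -> tuple[float, np.ndarray]:
    """Empirical ROC curve and trapezoidal AUC.

    The trapezoidal AUC over the empirical curve equals the Mann-Whitney U
    statistic normalised by n_pos * n_neg (ties contribute 1/2).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = labels == positive_label
    if y.all() or not y.any():
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, _ = roc_curve(y.astype(int), scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


# ---------------------------------------------------------------------------
# Leakage-safe pipeline: impute -> (optional) LRR denoise -> fuse -> SVM
# ---------------------------------------------------------------------------


@dataclass
class PipelineSpec:
    """Stage configuration for one train/apply pipeline."""

    imputer: str = "knn"  # knn | em | svd | mean
    knn_k: int = 5
    em_iters: int = 50
    svd_energy: float = 0.95
    denoise: bool = False
    lrr_lambda: float | None = None
    lrr_settings: SolverSettings | None = None
    fusion: str = "dca"  # dca | cca | concat
    energy_tol: float = 1e-8
    cca_ridge: float = 1e-3
    svm_c: float = 1.0
    standardize: bool = True

    def hash(self) -> str:
        payload = {
            k: (asdict(v) if isinstance(v, SolverSettings) else v)
            for k, v in asdict(self).items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


class FusionPipeline:
    """Fit-on-train / apply-to-test multimodal classification pipeline.

    Imputation, LRR denoising, fusion and the classifier are all fitted on
    the training modalities only; held-out samples are completed against the
    training pool, projected onto training-fold low-rank bases and transforms,
    then scored.
    """

    def __init__(self, spec: PipelineSpec):
        self.spec = spec
        self._imputers: list[dict] = []
        self._denoise_bases: list[np.ndarray] = []
        self._fuser = None
        self._scaler: StandardScaler | None = None
        self._svm: SVC | None = None
        self.positive_label = None

    # -- imputation ---------------------------------------------------------
    def _fit_impute(self, mod: ModalityMatrix) -> tuple[np.ndarray, dict]:
        s = self.spec
        state: dict = {"means": None}
        if s.imputer == "knn":
            res = knn_impute(mod, k=s.knn_k)
        elif s.imputer == "em":
            res = em_impute(mod, n_iter=s.em_iters)
            state["gaussian"] = res.model
        elif s.imputer == "svd":
            res = svd_impute(mod, energy=s.svd_energy)
            state["basis"] = res.basis
        elif s.imputer == "mean":
            res = mean_impute(mod)
        else:
            raise ValueError(f"unknown imputer {s.imputer!r}")
        state["train_completed"] = res.completed
        values, mask = _values_and_mask(mod)
        state["means"] = _feature_means(values, mask)
        return res.completed, state

    def _apply_impute(self, mod: ModalityMatrix, state: dict) -> np.ndarray:
        s = self.spec
        values, mask = _values_and_mask(mod)
        if not mask.any():
            return values.copy()
        if s.imputer == "knn":
            return knn_impute(mod, k=s.knn_k, reference=state["train_completed"]).completed
        if s.imputer == "em":
            model: GaussianModel = state["gaussian"]
            filled = np.where(mask, 0.0, values)
            return model.impute_columns(np.where(mask, filled, values), mask)
        if s.imputer == "svd":
            basis = state["basis"]
            if basis is None:
                basis = np.zeros((values.shape[0], 0))
            return project_onto_basis(basis, values, mask, state["means"])
        # mean
        completed = values.copy()
        rows, cols = np.nonzero(mask)
        completed[rows, cols] = state["means"][rows]
        return completed

    # -- denoising ----------------------------------------------------------
    @staticmethod
    def _column_space(denoised: np.ndarray, rel_tol: float = 1e-6) -> np.ndarray:
        u, sv, _ = np.linalg.svd(denoised, full_matrices=False)
        if sv.size == 0 or sv[0] == 0:
            return u[:, :0]
        rank = int(np.sum(sv > rel_tol * sv[0]))
        return u[:, :rank]

    def fit(self, modalities: list[ModalityMatrix], labels: np.ndarray) -> "FusionPipeline":
        s = self.spec
        labels = np.asarray(labels)
        classes = np.unique(labels)
        if classes.size != 2:
            raise ValueError("FusionPipeline evaluates binary tasks")
        self.positive_label = classes[1]

        self._imputers = []
        blocks: list[np.ndarray] = []
        for mod in modalities:
            completed, state = self._fit_impute(mod)
            self._imputers.append(state)
            blocks.append(completed)

        self._denoise_bases = []
        if s.denoise:
            denoised_blocks = []
            for block in blocks:
                sol = lrr_solve(block, lam=s.lrr_lambda, settings=s.lrr_settings)
                basis = self._column_space(sol.denoised)
                self._denoise_bases.append(basis)
                denoised_blocks.append(sol.denoised)
            blocks = denoised_blocks

        if len(blocks) == 1:
            fused = blocks[0]
            self._fuser = None
        elif s.fusion == "dca":
            self._fuser = MultisetDCA(energy_tol=s.energy_tol).fit(blocks, labels)
            fused = self._fuser.transform(blocks).values
        elif s.fusion == "cca":
            self._fuser = CCAFuser(ridge=s.cca_ridge).fit(blocks)
            fused = self._fuser.transform(blocks).values
        elif s.fusion == "concat":
            self._fuser = "concat"
            fused = np.vstack(blocks)
        else:
            raise ValueError(f"unknown fusion method {s.fusion!r}")

        x = fused.T  # sklearn rows-as-samples
        if s.standardize:
            self._scaler = StandardScaler().fit(x)
            x = self._scaler.transform(x)
        else:
            self._scaler = None
        self._svm = SVC(kernel="linear", C=s.svm_c).fit(x, labels)
        return self

    def _transform(self, modalities: list[ModalityMatrix]) -> np.ndarray:
        s = self.spec
        blocks = [
            self._apply_impute(mod, state)
            for mod, state in zip(modalities, self._imputers)
        ]
        if s.denoise:
            blocks = [
                basis @ (basis.T @ block) if basis.shape[1] else np.zeros_like(block)
                for basis, block in zip(self._denoise_bases, blocks)
            ]
        if self._fuser is None:
            fused = blocks[0]
        elif self._fuser == "concat":
            fused = np.vstack(blocks)
        else:
            fused = self._fuser.transform(blocks).values
        x = fused.T
        if self._scaler is not None:
            x = self._scaler.transform(x)
        return x

    def predict(self, modalities: list[ModalityMatrix]) -> np.ndarray:
        return self._svm.predict(self._transform(modalities))

    def decision_scores(self, modalities: list[ModalityMatrix]) -> np.ndarray:
        """Signed distance to the SVM hyperplane (positive-class oriented)."""
        return self._svm.decision_function(self._transform(modalities))

    def fitted_hash(self) -> str:
        """Hash of all fitted parameters — used to assert leakage-freedom."""
        h = hashlib.sha256()
        for state in self._imputers:
            h.update(np.ascontiguousarray(state["train_completed"]).tobytes())
        for basis in self._denoise_bases:
            h.update(np.ascontiguousarray(basis).tobytes())
        if isinstance(self._fuser, MultisetDCA):
            for t in self._fuser.stages:
                h.update(np.ascontiguousarray(t.W_a).tobytes())
                h.update(np.ascontiguousarray(t.W_b).tobytes())
        elif isinstance(self._fuser, CCAFuser):
            for pa, pb, mu_a, mu_b in self._fuser.stages:
                h.update(np.ascontiguousarray(pa).tobytes())
                h.update(np.ascontiguousarray(pb).tobytes())
        if self._svm is not None:
            h.update(np.ascontiguousarray(self._svm.coef_).tobytes())
            h.update(np.ascontiguousarray(self._svm.intercept_).tobytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# Repeated CV
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    per_fold: list[ConfusionMetrics]
    mean: dict[str, float]
    sd: dict[str, float]
    repeat_means: list[dict[str, float]]
    roc_points: np.ndarray
    auc: float
    fold_indices: list[np.ndarray]
    seed: int
    config_hash: str

    def summary(self) -> pd.DataFrame:
        rows = [
            {"metric": name, "mean": self.mean[name], "sd": self.sd[name]}
            for name in METRIC_NAMES
        ]
        rows.append({"metric": "AUC", "mean": self.auc, "sd": float("nan")})
        return pd.DataFrame(rows)


def _aggregate(per_fold: list[ConfusionMetrics]) -> tuple[dict, dict]:
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for name in METRIC_NAMES:
        vals = np.array([m.as_dict()[name] for m in per_fold])
        mean[name] = float(np.nanmean(vals))
        sd[name] = float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0
    return mean, sd


def repeated_cv(
    dataset: MultimodalDataset,
    spec: PipelineSpec,
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
    leaky: bool = False,
) -> CVResult:
    """Repeated stratified k-fold cross-validation of one pipeline.

    Each repeat uses a fresh stratified fold randomisation derived from
    ``seed``; metrics are aggregated over all ``n_folds * n_repeats`` test
    folds (mean +/- SD), with per-repeat means retained as a coarser
    aggregation. Decision scores are pooled over all folds for the ROC/AUC.

    With ``leaky=True`` imputation and denoising are performed once on the
    full dataset before splitting — a deliberately biased variant for
    measuring the effect of global preprocessing.
    """
    labels = np.asarray(dataset.labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError("repeated_cv evaluates one binary task at a time")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < n_folds={n_folds}; "
            "reduce n_folds"
        )
    positive = classes[1]

    work = dataset
    work_spec = spec
    if leaky:
        logger.warning("repeated_cv: leaky protocol — global preprocessing before CV")
        from dataclasses import replace

        pre = FusionPipeline(spec)
        blocks = []
        for mod in work.modalities:
            completed, _ = pre._fit_impute(mod)
            blocks.append(completed)
        if spec.denoise:
            blocks = [
                lrr_solve(b, lam=spec.lrr_lambda, settings=spec.lrr_settings).denoised
                for b in blocks
            ]
        mods = [
            ModalityMatrix(
                values=b,
                missing_mask=np.zeros_like(b, dtype=bool),
                name=m.name,
                feature_names=list(m.feature_names),
                sample_ids=list(m.sample_ids),
            )
            for b, m in zip(blocks, work.modalities)
        ]
        work = MultimodalDataset(mods, labels)
        work_spec = replace(spec, imputer="mean", denoise=False)

    per_fold: list[ConfusionMetrics] = []
    repeat_means: list[dict[str, float]] = []
    fold_indices: list[np.ndarray] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []

    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
        rep_fold_metrics: list[ConfusionMetrics] = []
        for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
            fold_indices.append(test_idx)
            train = work.subset(train_idx)
            test = work.subset(test_idx)
            pipe = FusionPipeline(work_spec).fit(train.modalities, train.labels)
            pred = pipe.predict(test.modalities)
            scores = pipe.decision_scores(test.modalities)
            m = confusion_metrics(test.labels, pred, positive)
            per_fold.append(m)
            rep_fold_metrics.append(m)
            pooled_scores.append(scores)
            pooled_labels.append(test.labels)
        rep_mean, _ = _aggregate(rep_fold_metrics)
        repeat_means.append(rep_mean)

    mean, sd = _aggregate(per_fold)
    auc, roc_points = roc_auc(
        np.concatenate(pooled_scores), np.concatenate(pooled_labels), positive
    )
    return CVResult(
        per_fold=per_fold,
        mean=mean,
        sd=sd,
        repeat_means=repeat_means,
        roc_points=roc_points,
        auc=auc,
        fold_indices=fold_indices,
        seed=seed,
        config_hash=spec.hash(),
    )


# ---------------------------------------------------------------------------
# Method comparison
# ---------------------------------------------------------------------------

# Named pipelines: the LRR+DCA fusion pipeline and its comparison baselines.
# "ldf" imputes with KNN (K=5), LRR-denoises each modality and fuses with DCA;
# the impute-then-concatenate baselines use EM (50 iterations), KNN (K=7) and
# iterative SVD (95% energy); "cca" and "concat" impute with KNN (K=5).
METHOD_REGISTRY: dict[str, PipelineSpec] = {
    "ldf": PipelineSpec(imputer="knn", knn_k=5, denoise=True, fusion="dca"),
    "knn": PipelineSpec(imputer="knn", knn_k=7, fusion="concat"),
    "em": PipelineSpec(imputer="em", em_iters=50, fusion="concat"),
    "svd": PipelineSpec(imputer="svd", svd_energy=0.95, fusion="concat"),
    "cca": PipelineSpec(imputer="knn", knn_k=5, fusion="cca"),
    "concat": PipelineSpec(imputer="knn", knn_k=5, fusion="concat"),
}


def binary_task(dataset: MultimodalDataset, class_a, class_b) -> MultimodalDataset:
    """Subset a multiclass dataset to one pairwise task."""
    labels = np.asarray(dataset.labels)
    idx = np.nonzero((labels == class_a) | (labels == class_b))[0]
    if idx.size == 0:
        raise ValueError(f"no samples for classes {class_a!r}/{class_b!r}")
    return dataset.subset(idx)


def compare_methods(
    dataset: MultimodalDataset,
    methods: list[str],
    tasks: list[tuple] | None = None,
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], CVResult]]:
    """Run several named pipelines over pairwise tasks with identical folds.

    Returns a tidy table (method, task, metric, mean, sd) and the underlying
    CVResult per (method, task). All methods see the same fold randomisation
    (same seed), giving a paired design.
    """
    unknown = [m for m in methods if m not in METHOD_REGISTRY]
    if unknown:
        raise ValueError(
            f"unknown methods {unknown}; valid names: {sorted(METHOD_REGISTRY)}"
        )
    classes = list(np.unique(dataset.labels))
    if tasks is None:
        tasks = [
            (classes[i], classes[j])
            for i in range(len(classes))
            for j in range(i + 1, len(classes))
        ]
    rows = []
    results: dict[tuple[str, str], CVResult] = {}
    for a, b in tasks:
        task_name = f"{a}-vs-{b}"
        sub = binary_task(dataset, a, b)
        for method in methods:
            res = repeated_cv(
                sub, METHOD_REGISTRY[method], n_folds=n_folds, n_repeats=n_repeats, seed=seed
            )
            results[(method, task_name)] = res
            for metric in METRIC_NAMES:
                rows.append(
                    {
                        "method": method,
                        "task": task_name,
                        "metric": metric,
                        "mean": res.mean[metric],
                        "sd": res.sd[metric],
                    }
                )
            rows.append(
                {
                    "method": method,
                    "task": task_name,
                    "metric": "AUC",
                    "mean": res.auc,
                    "sd": float("nan"),
                }
            )
    return pd.DataFrame(rows), results
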