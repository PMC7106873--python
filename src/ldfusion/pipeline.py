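"""Tabular I/O, configuration and the end-to-end workflow.

CSV interfaces are samples-as-rows (first column = sample ID, header row of
feature names); internally everything is transposed to the columns-as-samples
convention of the math modules. Missing entries are the configurable token
(default ``NA``) or an empty cell.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datasets import (
    ModalityMatrix,
    MultimodalDataset,
    SimulationConfig,
    config_to_dict,
    generate,
)
from .evaluate import METHOD_REGISTRY, PipelineSpec, compare_methods

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "DataError",
    "PipelineConfig",
    "RunManifest",
    "load_tables",
    "write_dataset",
    "run_pipeline",
]


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Malformed or inconsistent input tables (CLI exit code 3)."""


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def read_modality_csv(
    path: str | Path, name: str | None = None, missing_token: str = "NA"
) -> ModalityMatrix:
    """Read one modality CSV (rows = samples, first column = sample ID)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise DataError(f"{path}: need a sample-ID column plus >= 1 feature column")
    ids = df.iloc[:, 0].astype(str).tolist()
    dupes = pd.Series(ids)[pd.Series(ids).duplicated()].unique()
    if len(dupes):
        raise DataError(f"{path}: duplicate sample IDs: {list(dupes)[:5]}")
    feats = df.columns[1:].tolist()
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=float)
    mask = np.zeros(raw.shape, dtype=bool)
    for (i, j), cell in np.ndenumerate(raw):
        cell = str(cell).strip()
        if cell == "" or cell == missing_token:
            values[i, j] = np.nan
            mask[i, j] = True
            continue
        try:
            values[i, j] = float(cell)
        except ValueError as exc:
            raise DataError(
                f"{path}: non-numeric cell {cell!r} at row {ids[i]!r}, "
                f"column {feats[j]!r} (missing token is {missing_token!r})"
            ) from exc
    return ModalityMatrix(
        values=values.T,
        missing_mask=mask.T,
        name=name or path.stem,
        feature_names=feats,
        sample_ids=ids,
    )


def load_tables(
    modality_paths: dict[str, str | Path],
    labels_path: str | Path,
    missing_token: str = "NA",
) -> MultimodalDataset:
    """Load and align modality CSVs and a labels CSV by sample ID.

    Samples are aligned on the ID intersection across all modalities and the
    labels table; per-modality drops are logged (a real cohort rarely has all
    modalities for all subjects).
    """
    mods = {
        name: read_modality_csv(p, name=name, missing_token=missing_token)
        for name, p in modality_paths.items()
    }
    ldf = pd.read_csv(labels_path, dtype=str, keep_default_na=False)
    if ldf.shape[1] < 2:
        raise DataError(f"{labels_path}: need sample-ID and label columns")
    if ldf.iloc[:, 0].duplicated().any():
        raise DataError(f"{labels_path}: duplicate sample IDs")
    label_map = dict(zip(ldf.iloc[:, 0].astype(str), ldf.iloc[:, 1].astype(str)))

    common = set(label_map)
    for m in mods.values():
        common &= set(m.sample_ids)
    if not common:
        raise DataError("no sample IDs common to all modalities and the labels table")
    # stable order: follow the first modality's order
    first = next(iter(mods.values()))
    ordered = [sid for sid in first.sample_ids if sid in common]
    for name, m in mods.items():
        dropped = len(m.sample_ids) - len(ordered)
        if dropped:
            logger.info("load_tables: %s drops %d samples outside the ID intersection", name, dropped)

    aligned = []
    for name, m in mods.items():
        pos = {sid: i for i, sid in enumerate(m.sample_ids)}
        idx = np.array([pos[sid] for sid in ordered])
        aligned.append(
            ModalityMatrix(
                values=m.values[:, idx],
                missing_mask=m.missing_mask[:, idx],
                name=name,
                feature_names=list(m.feature_names),
                sample_ids=list(ordered),
            )
        )
    labels = np.array([label_map[sid] for sid in ordered])
    return MultimodalDataset(aligned, labels)


def write_dataset(
    dataset: MultimodalDataset,
    out_dir: str | Path,
    missing_token: str = "NA",
    ground_truth: bool = False,
) -> list[Path]:
    """Write one CSV per modality plus a labels CSV (and optional ground truth)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for m in dataset.modalities:
        df = pd.DataFrame(m.values.T, columns=m.feature_names)
        df = df.astype(object).where(~m.missing_mask.T, missing_token)
        df.insert(0, "sample_id", m.sample_ids)
        p = out_dir / f"{m.name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    labels = pd.DataFrame({"sample_id": dataset.sample_ids, "label": dataset.labels})
    p = out_dir / "labels.csv"
    labels.to_csv(p, index=False)
    written.append(p)
    if ground_truth and dataset.ground_truth is not None:
        gt_dir = out_dir / "ground_truth"
        gt_dir.mkdir(exist_ok=True)
        for m, clean, cols in zip(
            dataset.modalities,
            dataset.ground_truth.clean,
            dataset.ground_truth.corrupt_columns,
        ):
            df = pd.DataFrame(clean.T, columns=m.feature_names)
            df.insert(0, "sample_id", m.sample_ids)
            p = gt_dir / f"{m.name}_clean.csv"
            df.to_csv(p, index=False)
            written.append(p)
            p = gt_dir / f"{m.name}_corrupt_columns.csv"
            pd.DataFrame({"column": cols}).to_csv(p, index=False)
            written.append(p)
    return written


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "simulate",
    "inputs",
    "method",
    "impute",
    "denoise",
    "fuse",
    "svm",
    "cv",
    "tasks",
    "seed",
    "output_dir",
    "missing_token",
    "leaky",
}


@dataclass
class PipelineConfig:
    """Validated configuration for a full run.

    Either ``simulate`` (a :class:`SimulationConfig`) or ``inputs``
    (``{"modalities": {name: path}, "labels": path}``) provides the data.
    """

    output_dir: str
    simulate: SimulationConfig | None = None
    inputs: dict | None = None
    method: str = "ldf"
    seed: int = 0
    n_folds: int = 10
    n_repeats: int = 10
    tasks: list[tuple] | None = None
    missing_token: str = "NA"
    leaky: bool = False
    spec_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if ("simulate" in raw) == ("inputs" in raw):
            raise ConfigError("config needs exactly one of 'simulate' or 'inputs'")
        if "output_dir" not in raw:
            raise ConfigError("config key 'output_dir' is required")
        sim = None
        if "simulate" in raw:
            sim_raw = dict(raw["simulate"])
            try:
                sim = SimulationConfig(**sim_raw)
                sim.validate()
            except TypeError as exc:
                raise ConfigError(f"invalid simulate block: {exc}") from exc
            except ValueError as exc:
                raise ConfigError(str(exc)) from exc
        method = raw.get("method", "ldf")
        if method not in METHOD_REGISTRY:
            raise ConfigError(
                f"unknown method {method!r}; valid: {sorted(METHOD_REGISTRY)}"
            )
        cv = raw.get("cv", {})
        overrides = {}
        for block in ("impute", "denoise", "fuse", "svm"):
            if block in raw:
                overrides.update(raw[block])
        cfg = cls(
            output_dir=str(raw["output_dir"]),
            simulate=sim,
            inputs=raw.get("inputs"),
            method=method,
            seed=int(raw.get("seed", 0)),
            n_folds=int(cv.get("folds", 10)),
            n_repeats=int(cv.get("repeats", 10)),
            tasks=[tuple(t) for t in raw["tasks"]] if raw.get("tasks") else None,
            missing_token=str(raw.get("missing_token", "NA")),
            leaky=bool(raw.get("leaky", False)),
            spec_overrides=overrides,
        )
        if cfg.n_folds < 2:
            raise ConfigError("cv.folds must be >= 2")
        if cfg.n_repeats < 1:
            raise ConfigError("cv.repeats must be >= 1")
        return cfg

    def resolved(self) -> dict:
        d = {
            "output_dir": self.output_dir,
            "method": self.method,
            "seed": self.seed,
            "cv": {"folds": self.n_folds, "repeats": self.n_repeats},
            "tasks": [list(t) for t in self.tasks] if self.tasks else None,
            "missing_token": self.missing_token,
            "leaky": self.leaky,
            "overrides": self.spec_overrides,
        }
        if self.simulate is not None:
            d["simulate"] = config_to_dict(self.simulate)
        if self.inputs is not None:
            d["inputs"] = self.inputs
        return d

    def pipeline_spec(self) -> PipelineSpec:
        spec = dataclasses.replace(METHOD_REGISTRY[self.method])
        for key, value in self.spec_overrides.items():
            if not hasattr(spec, key):
                raise ConfigError(f"unknown pipeline parameter {key!r}")
            setattr(spec, key, value)
        return spec


@dataclass
class RunManifest:
    config: dict
    version: str
    stage_seconds: dict[str, float]
    warnings: list[str]
    checksums: dict[str, str]

    def write(self, path: str | Path) -> None:
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
        tmp.replace(path)  # atomic on the same filesystem


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(self.format(record))


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full workflow: obtain data, evaluate the configured method
    under repeated leakage-safe CV on every pairwise task, and write the
    metrics, per-fold, and ROC CSVs plus a run manifest."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    collector.setFormatter(logging.Formatter("%(name)s: %(message)s"))
    logging.getLogger("ldfusion").addHandler(collector)
    stage_seconds: dict[str, float] = {}
    written: list[Path] = []
    try:
        t0 = time.perf_counter()
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate)
            dataset = generate(sim)
        else:
            inputs = config.inputs or {}
            if "modalities" not in inputs or "labels" not in inputs:
                raise ConfigError("inputs must provide 'modalities' and 'labels'")
            dataset = load_tables(
                inputs["modalities"], inputs["labels"], config.missing_token
            )
        stage_seconds["load"] = time.perf_counter() - t0

        spec = config.pipeline_spec()
        t0 = time.perf_counter()
        methods = [config.method]
        if config.leaky:
            from .evaluate import repeated_cv, METRIC_NAMES

            rows = []
            results = {}
            classes = list(np.unique(dataset.labels))
            tasks = config.tasks or [
                (classes[i], classes[j])
                for i in range(len(classes))
                for j in range(i + 1, len(classes))
            ]
            from .evaluate import binary_task

            for a, b in tasks:
                res = repeated_cv(
                    binary_task(dataset, a, b),
                    spec,
                    n_folds=config.n_folds,
                    n_repeats=config.n_repeats,
                    seed=config.seed,
                    leaky=True,
                )
                results[(config.method, f"{a}-vs-{b}")] = res
                for metric in METRIC_NAMES:
                    rows.append(
                        {
                            "method": config.method,
                            "task": f"{a}-vs-{b}",
                            "metric": metric,
                            "mean": res.mean[metric],
                            "sd": res.sd[metric],
                        }
                    )
            table = pd.DataFrame(rows)
        else:
            # paired evaluation through the shared protocol
            from .evaluate import METHOD_REGISTRY as registry

            saved = registry[config.method]
            registry[config.method] = spec
            try:
                table, results = compare_methods(
                    dataset,
                    methods,
                    tasks=config.tasks,
                    n_folds=config.n_folds,
                    n_repeats=config.n_repeats,
                    seed=config.seed,
                )
            finally:
                registry[config.method] = saved
        stage_seconds["evaluate"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        metrics_path = out_dir / "metrics.csv"
        table.to_csv(metrics_path, index=False)
        written.append(metrics_path)

        fold_rows = []
        roc_rows = []
        for (method, task), res in results.items():
            for i, m in enumerate(res.per_fold):
                row = {"method": method, "task": task, "fold": i}
                row.update(m.as_dict())
                fold_rows.append(row)
            for fpr, tpr in res.roc_points:
                roc_rows.append(
                    {"method": method, "task": task, "fpr": fpr, "tpr": tpr, "auc": res.auc}
                )
        folds_path = out_dir / "per_fold.csv"
        pd.DataFrame(fold_rows).to_csv(folds_path, index=False)
        written.append(folds_path)
        roc_path = out_dir / "roc_points.csv"
        pd.DataFrame(roc_rows).to_csv(roc_path, index=False)
        written.append(roc_path)
        stage_seconds["write"] = time.perf_counter() - t0

        manifest = RunManifest(
            config=config.resolved(),
            version=__version__,
            stage_seconds=stage_seconds,
            warnings=list(collector.messages),
            checksums={p.name: _sha256(p) for p in written},
        )
        manifest.write(out_dir / "manifest.json")
        return manifest
    except Exception:
        partial = RunManifest(
            config=config.resolved(),
            version=__version__,
            stage_seconds=stage_seconds,
            warnings=list(collector.messages),
            checksums={p.name: _sha256(p) for p in written if p.exists()},
        )
        partial.write(out_dir / "manifest.partial.json")
        raise
    finally:
        logging.getLogger("ldfusion").removeHandler(collector)
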