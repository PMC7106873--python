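"""Synthetic multimodal datasets and core containers.

Real studies of this kind draw on cohorts such as ADNI-1, where each subject
contributes up to three feature blocks (93 MRI region-of-interest features,
93 PET features, 3 CSF biomarkers) and a diagnostic label (NC / MCI / AD).
Those tables are access-restricted, so this module generates datasets with
the same statistical skeleton: a low-rank, class-discriminative latent signal
shared across modalities, dense Gaussian noise, column-sparse gross
corruptions (whole samples within a modality), and missing-at-random entries.

All matrices follow the columns-as-samples convention: a modality block is
``d_features x n_samples``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "ModalityMatrix",
    "MultimodalDataset",
    "GroundTruth",
    "generate",
    "mask_report",
]

DEFAULT_MODALITY_NAMES = ("MRI", "PET", "CSF")


class ConfigError(ValueError):
    """Invalid configuration value; message names the offending field."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multimodal generator.

    Parameters
    ----------
    n_per_class:
        Samples per class (>= 2).
    n_classes:
        Number of diagnostic classes; 3 mirrors NC/MCI/AD.
    modality_dims:
        Feature count per modality; the default ``[93, 93, 3]`` mirrors the
        MRI/PET/CSF feature-table shape.
    latent_rank:
        Dimension of the latent subspace shared by all modalities.
    class_separation:
        Effect size: Euclidean shift of each class's latent mean from the
        latent origin. 0 gives label-free (null) data.
    noise_sd:
        Standard deviation of dense i.i.d. Gaussian noise added to every entry.
    corrupt_frac:
        Fraction of sample columns per modality receiving gross corruption
        (additive Gaussian with ``corrupt_sd``) on the whole column.
    corrupt_sd:
        Corruption magnitude.
    missing_frac:
        Per-modality fraction of entries masked as missing. Masking is
        exact-count: ``floor(missing_frac * d * n)`` distinct cells.
    block_missing:
        If True, missingness is whole-modality-per-sample instead of
        entry-level: ``floor(missing_frac * n)`` sample columns are fully
        masked in each modality.
    seed:
        Seed for all randomness.
    """

    n_per_class: int = 40
    n_classes: int = 3
    modality_dims: Sequence[int] = (93, 93, 3)
    latent_rank: int = 5
    class_separation: float = 1.0
    noise_sd: float = 0.2
    corrupt_frac: float = 0.0
    corrupt_sd: float = 2.0
    missing_frac: float = 0.0
    block_missing: bool = False
    seed: int = 0
    modality_names: Sequence[str] | None = None

    def validate(self) -> None:
        if self.n_per_class < 2:
            raise ConfigError("n_per_class must be >= 2")
        if self.n_classes < 1:
            raise ConfigError("n_classes must be >= 1")
        if self.latent_rank < 1:
            raise ConfigError("latent_rank must be >= 1")
        if not self.modality_dims or any(d < 1 for d in self.modality_dims):
            raise ConfigError("modality_dims must all be >= 1")
        for name in ("corrupt_frac", "missing_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("noise_sd", "corrupt_sd", "class_separation"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.modality_names is not None and len(self.modality_names) != len(
            self.modality_dims
        ):
            raise ConfigError("modality_names length must match modality_dims")

    def resolved_names(self) -> list[str]:
        if self.modality_names is not None:
            return list(self.modality_names)
        names = list(DEFAULT_MODALITY_NAMES[: len(self.modality_dims)])
        while len(names) < len(self.modality_dims):
            names.append(f"modality{len(names)}")
        return names


@dataclass
class ModalityMatrix:
    """One modality's feature block, columns-as-samples (d x n).

    Missing entries are NaN in ``values`` and True in ``missing_mask``.
    """

    values: np.ndarray
    missing_mask: np.ndarray
    name: str = "modality"
    feature_names: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D d x n matrix")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape must equal values shape")
        d, n = self.values.shape
        if not self.feature_names:
            self.feature_names = [f"{self.name}_f{i}" for i in range(d)]
        if not self.sample_ids:
            self.sample_ids = [f"s{j}" for j in range(n)]
        if len(self.feature_names) != d:
            raise ValueError("feature_names length must equal feature count")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must equal sample count")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def copy(self) -> "ModalityMatrix":
        return ModalityMatrix(
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
            name=self.name,
            feature_names=list(self.feature_names),
            sample_ids=list(self.sample_ids),
        )


@dataclass
class GroundTruth:
    """Clean signal and perturbation bookkeeping for a generated dataset."""

    clean: list[np.ndarray]
    corrupt_columns: list[np.ndarray]
    missing_masks: list[np.ndarray]


@dataclass
class MultimodalDataset:
    """Aligned modality matrices plus one class label per sample."""

    modalities: list[ModalityMatrix]
    labels: np.ndarray
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        counts = {m.n_samples for m in self.modalities}
        if len(counts) > 1:
            raise ValueError("all modalities must share the same sample count")
        n = self.modalities[0].n_samples if self.modalities else 0
        if len(self.labels) != n:
            raise ValueError("labels length must equal sample count")
        ids = self.modalities[0].sample_ids if self.modalities else []
        for m in self.modalities[1:]:
            if m.sample_ids != ids:
                raise ValueError("all modalities must share sample ordering")

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    @property
    def sample_ids(self) -> list[str]:
        return self.modalities[0].sample_ids

    def modality(self, name: str) -> ModalityMatrix:
        for m in self.modalities:
            if m.name == name:
                return m
        raise KeyError(f"no modality named {name!r}")

    def subset(self, idx: np.ndarray) -> "MultimodalDataset":
        """Column subset (samples) by integer index; ground truth is dropped."""
        idx = np.asarray(idx)
        mods = [
            ModalityMatrix(
                values=m.values[:, idx],
                missing_mask=m.missing_mask[:, idx],
                name=m.name,
                feature_names=list(m.feature_names),
                sample_ids=[m.sample_ids[i] for i in idx],
            )
            for m in self.modalities
        ]
        return MultimodalDataset(mods, self.labels[idx])

    def copy(self) -> "MultimodalDataset":
        return MultimodalDataset(
            [m.copy() for m in self.modalities], self.labels.copy(), self.ground_truth
        )


def _class_latent_means(rng: np.random.Generator, c: int, r: int, sep: float) -> np.ndarray:
    """Class means in latent space: random directions, centred, unit length x sep."""
    if sep == 0.0 or c == 1:
        # keep RNG stream consumption identical regardless of separation
        rng.normal(size=(c, r))
        return np.zeros((c, r))
    m = rng.normal(size=(c, r))
    m -= m.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return sep * m / norms


def generate(config: SimulationConfig) -> MultimodalDataset:
    """Generate a multimodal dataset with shared low-rank class structure.

    For each modality ``m`` with dimension ``d_m`` the clean block is
    ``L_m @ (Z + mu_class)`` with ``Z`` a ``latent_rank x n`` standard-normal
    latent matrix shared across modalities, ``mu_class`` the per-class latent
    mean shift, and ``L_m`` a random ``d_m x latent_rank`` loading. Observed
    data add dense Gaussian noise and column-sparse corruption, then masking.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    c, r = config.n_classes, config.latent_rank
    n = config.n_per_class * c
    labels = np.repeat(np.arange(c), config.n_per_class)

    mu = _class_latent_means(rng, c, r, config.class_separation)  # c x r
    z = rng.normal(size=(r, n)) + mu[labels].T  # latent scores, r x n
    sample_ids = [f"s{j:04d}" for j in range(n)]

    names = config.resolved_names()
    modalities: list[ModalityMatrix] = []
    clean_blocks: list[np.ndarray] = []
    corrupt_cols: list[np.ndarray] = []
    masks: list[np.ndarray] = []

    for name, d in zip(names, config.modality_dims):
        loading = rng.normal(size=(d, r)) / np.sqrt(r)
        clean = loading @ z
        observed = clean + rng.normal(scale=config.noise_sd, size=(d, n))

        n_corrupt = int(np.floor(config.corrupt_frac * n))
        cols = np.sort(rng.choice(n, size=n_corrupt, replace=False))
        if n_corrupt:
            observed[:, cols] += rng.normal(scale=config.corrupt_sd, size=(d, n_corrupt))

        mask = np.zeros((d, n), dtype=bool)
        if config.block_missing:
            n_blocked = int(np.floor(config.missing_frac * n))
            blocked = rng.choice(n, size=n_blocked, replace=False)
            mask[:, blocked] = True
        else:
            n_miss = int(np.floor(config.missing_frac * d * n))
            flat = rng.choice(d * n, size=n_miss, replace=False)
            mask.flat[flat] = True
        values = observed.copy()
        values[mask] = np.nan

        modalities.append(
            ModalityMatrix(
                values=values,
                missing_mask=mask,
                name=name,
                feature_names=[f"{name}_f{i}" for i in range(d)],
                sample_ids=list(sample_ids),
            )
        )
        clean_blocks.append(clean)
        corrupt_cols.append(cols)
        masks.append(mask)

    return MultimodalDataset(
        modalities=modalities,
        labels=labels,
        ground_truth=GroundTruth(clean_blocks, corrupt_cols, masks),
    )


def mask_report(dataset: MultimodalDataset) -> tuple[dict[str, int], pd.DataFrame]:
    """Missing-entry counts per modality and a per-sample availability table.

    A sample is "available" in a modality when at least one of its entries is
    observed (whole-block missingness makes a sample unavailable).
    """
    counts = {m.name: m.n_missing() for m in dataset.modalities}
    avail = pd.DataFrame(
        {m.name: ~m.missing_mask.all(axis=0) for m in dataset.modalities},
        index=pd.Index(dataset.sample_ids, name="sample_id"),
    )
    avail["n_available"] = avail.sum(axis=1)
    return counts, avail


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["modality_dims"] = list(d["modality_dims"])
    if d["modality_names"] is not None:
        d["modality_names"] = list(d["modality_names"])
    return d
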