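import numpy as np
import pytest

from ldfusion import SimulationConfig, generate
from ldfusion.datasets import ModalityMatrix


@pytest.fixture(scope="session")
def small_dataset():
    """Three modalities, three classes, moderate signal, no perturbations."""
    cfg = SimulationConfig(
        n_per_class=20,
        n_classes=3,
        modality_dims=[20, 15, 3],
        latent_rank=4,
        class_separation=1.5,
        noise_sd=0.2,
        seed=7,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def masked_lowrank():
    """Rank-2 noisy matrix with 5% masked cells and its ground truth."""
    rng = np.random.default_rng(21)
    d, n, r = 30, 60, 2
    truth = rng.normal(size=(d, r)) @ rng.normal(size=(r, n)) + rng.normal(
        scale=0.1, size=(d, n)
    )
    mask = np.zeros((d, n), dtype=bool)
    mask.flat[rng.choice(d * n, int(0.05 * d * n), replace=False)] = True
    values = truth.copy()
    values[mask] = np.nan
    return ModalityMatrix(values, mask), truth, mask
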