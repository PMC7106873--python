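# ldfusion

Feature-level fusion of multimodal biomedical feature tables for disease
classification, built around two linear-algebraic workhorses:

* **Low-rank representation (LRR)** denoising — per modality, solve

  $$\min_{X,E}\ \|X\|_* + \lambda\,\|E\|_{2,1}
    \quad\text{s.t.}\quad A = AX + E,$$

  where $\|X\|_*$ is the nuclear norm and $\|E\|_{2,1}$ the sum of column
  Euclidean norms. $AX$ captures the self-expressive low-rank signal shared
  by the samples; $E$ collects column-sparse gross corruption (whole bad
  samples). Solved by the standard inexact augmented Lagrange multiplier
  scheme with singular-value thresholding and column-wise shrinkage.

* **Discriminant correlation analysis (DCA)** fusion — for two feature sets
  $A$ ($p\times n$) and $B$ ($q\times n$) with class labels, whiten each
  set's between-class scatter
  $S_{\text{inter}} = \Phi\Phi^{\mathsf T}$,
  $\Phi = [\sqrt{m_1}(\bar a_1-\bar a),\dots,\sqrt{m_c}(\bar a_c-\bar a)]$,
  then diagonalise the transformed between-class cross-covariance by SVD
  ($W_{ca}=U\Sigma^{-1/2}$, $W_{cb}=V\Sigma^{-1/2}$), project
  ($A^* = W_aA$, $B^* = W_bB$) and concatenate $A^*$, $B^*$ in series.
  The fused dimension per pair is at most $2(c-1)$; three or more
  modalities are fused by a left-fold cascade.

Around these sit KNN inverse-distance completion of missing entries (with
EM-Gaussian and iterative-SVD baselines), a CCA fusion baseline, and a
leakage-safe evaluation protocol: linear SVM under stratified 10-fold
cross-validation repeated 10 times, reporting ACC/SEN/SPE/BAC/PPV/NPV
(mean ± SD over folds) plus a pooled ROC curve and AUC.

The intended data are cohort-style per-subject feature tables — e.g. MRI
region-of-interest volumes, PET intensities and CSF biomarkers with
diagnostic labels (normal control / mild cognitive impairment / Alzheimer's
disease). Such cohorts are access-restricted, so the package ships a
synthetic generator that emulates their statistical skeleton (three aligned
modality blocks of 93/93/3 features with shared low-rank class structure,
dense noise, corrupted sample columns, missing entries) and makes every
stage testable end to end.

## Worked example

```python
from ldfusion import SimulationConfig, generate, repeated_cv
from ldfusion.evaluate import binary_task, METHOD_REGISTRY

cfg = SimulationConfig(
    n_per_class=40, modality_dims=[93, 93, 3], latent_rank=5,
    class_separation=1.5, noise_sd=0.3,
    corrupt_frac=0.1, corrupt_sd=3.0, missing_frac=0.05, seed=42,
)
dataset = generate(cfg)                    # 120 samples, 3 classes

task = binary_task(dataset, 0, 2)          # the NC-like vs AD-like pair
result = repeated_cv(task, METHOD_REGISTRY["ldf"],
                     n_folds=10, n_repeats=2, seed=1)
print(result.summary().to_string(index=False))
```

```
metric     mean       sd
   ACC 0.850000 0.143957
   SEN 0.875000 0.190221
   SPE 0.825000 0.200329
   BAC 0.850000 0.143957
   PPV 0.851905 0.157470
   NPV 0.893333 0.161987
   AUC 0.932813      NaN
```

Each row is one confusion metric averaged over the 20 test folds (10 folds
× 2 repeats): the full pipeline — KNN completion of the 5% missing cells,
LRR denoising of each modality inside every training fold, DCA fusion to a
4-dimensional discriminant space, linear SVM — separates the two simulated
classes with 85% accuracy and AUC 0.93 despite 10% grossly corrupted
samples. The SD column shows fold-to-fold spread; AUC is computed once from
the pooled decision scores.

The same pipeline is available from the shell:

```sh
ldfusion simulate --n-per-class 40 --missing-frac 0.05 --seed 42 --out data/
ldfusion run --config config.yaml --seed 1
```

with `impute`, `denoise`, `fuse` and `evaluate` subcommands for the
individual stages (see `ldfusion --help`).

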