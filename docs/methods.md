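# Methods

## Problem setting

The package targets multimodal diagnosis from per-subject feature tables:
each subject contributes up to three numeric feature blocks (e.g. 93 MRI
region-of-interest features, 93 PET features, 3 CSF biomarkers) and one
class label. Three difficulties shape the design: entries are missing
(subjects skip modalities or assays), some samples are grossly corrupted
(acquisition artefacts), and the useful signal is a low-dimensional
structure shared across modalities rather than any single feature. The
pipeline therefore runs completion → low-rank denoising → discriminant
fusion → classification, in that order.

All internal linear algebra uses the columns-as-samples convention
(`d features × n samples`); the CSV interfaces are samples-as-rows for
tabular ergonomics and are transposed on load.

## Missing-value completion

**KNN (pipeline default).** A missing entry $(i,j)$ is replaced by the
inverse-distance-weighted mean of the $K$ nearest donor samples' observed
values at feature $i$, weights $w_k = (1/d_k)/\sum_l (1/d_l)$. Distances
are Euclidean over co-observed coordinates, rescaled by
$\sqrt{d/\#\text{co-observed}}$ so pairs with few shared coordinates are
not artificially close. Decisions the weight formula does not make:

* a donor at distance zero is an exact match and wins outright (the
  $1/d$ weight is undefined there); ties among exact matches are averaged;
* fewer than $K$ usable donors → all available donors, with a logged
  warning; no donor at all → donor-pool feature mean, with a warning;
* $K=5$ in the fused pipeline and $K=7$ for the standalone
  KNN-impute-then-concatenate baseline — both conventions appear in
  practice, and both are exposed as parameters.

**EM (baseline).** Iterated Gaussian conditional-mean imputation: fit mean
and covariance over samples, replace each sample's missing block by its
conditional mean given the observed block, iterate (default 50 rounds,
stopping early when the largest imputed-entry change falls below 1e-8).
The covariance carries a ridge of $10^{-6}\,\mathrm{tr}(S)/d$ against
singularity when $d \gtrsim n$. The 1e-8 tolerance is chosen so that an
exactly linearly-determined cell is recovered to ~1e-7 rather than
stalling at the looser 1e-6 iterate-change level.

**Iterative SVD (baseline).** Fill missing entries with feature means,
then alternate: truncate the SVD to the smallest rank whose cumulative
squared singular values reach the energy fraction (default 95%), refresh
the missing entries from the truncation, until the relative change of
imputed entries drops below 1e-7. With energy 1.0 the truncation is
lossless and the initial fill is a fixed point.

All completers leave observed entries bit-identical.

## Low-rank representation

Per modality, the program
$\min \|X\|_* + \lambda\|E\|_{2,1}$ s.t. $A = AX + E$
is solved by inexact ALM with the auxiliary split $J = X$ (singular-value
thresholding for $J$, a cached Cholesky solve of $(I + A^{\mathsf T}A)$
for $X$, column shrinkage for $E$, dual and penalty updates). Defaults:
$\mu_0 = 10^{-2}$, $\rho = 1.1$, $\mu_{\max} = 10^6$, relative residual
tolerance $10^{-6}$, 500 iterations cap; in practice convergence takes
under 100 iterations at the sizes used here. Default
$\lambda = 1/\sqrt{\max(d,n)}$ (robust-PCA-style heuristic), configurable
per modality. The **denoised output is $AX$**, not $A - E$; the two differ
before full convergence and $AX$ is used consistently downstream.

Two behaviours worth knowing:

* **Corruption detection needs a smaller λ than denoising.** Because $A$
  itself is the self-expression dictionary, a large-norm corrupted column
  can absorb itself into $AX$ when λ is large, leaving $E$ empty exactly
  where it should flag. `detect_corrupted_columns` therefore selects λ on
  a small grid (0.1–2× the default) by an unsupervised criterion:
  maximise the gap between the mean $E$-column norm of the expected
  top-fraction and the remainder. Only the expected corruption rate
  enters; true corruption indices never do.
* **Tiny-norm sample columns can land in $E$.** The L2,1 prox zeroes any
  column whose residual norm is below $\lambda/\mu$-scale thresholds, so a
  sample lying near the origin may be absorbed into $E$ even in noiseless
  data. This is the correct optimum of the convex program, not a solver
  failure; "denoised ≈ observed on clean data" holds for blocks whose
  columns have non-degenerate norms.

On noiseless rank-$r$ input the solution matches the closed-form
shape-interaction matrix $V_rV_r^{\mathsf T}$ of the skinny SVD; the test
suite and acceptance script verify this to 1e-3 elementwise (observed
~1e-9).

## Discriminant correlation analysis

The between-class scatter uses $\sqrt{m_j}$-weighted class-mean deviations
(class-size weighting; an unweighted variant is exposed). Whitening is done
in the small $c \times c$ space: with $\Phi^{\mathsf T}\Phi = Q\Lambda
Q^{\mathsf T}$, $W_{\text{inter}} = \Phi Q\Lambda^{-1}$ satisfies
$W^{\mathsf T}(\Phi\Phi^{\mathsf T})W = I_r$, keeping eigenpairs above
1e-8 of the largest eigenvalue (drop numerically-zero directions).

The cross-set step diagonalises the **between-class** cross-covariance of
the whitened sets, $S'_{ab} = \Phi'_a{\Phi'_b}^{\mathsf T}$, by SVD. Using
the between-class construction (rather than the raw transformed data
matrices) was a genuinely open design choice; it was adopted because it
makes the transform exactly invariant to adding a constant vector to all
samples of a set (means cancel), bounds the fused dimension by $c-1$ per
set by construction, and satisfies the defining identity
$W_{ca}^{\mathsf T} S'_{ab} W_{cb} = I_r$ regardless of input. SVD signs
are fixed (largest-magnitude entry of each left singular vector positive,
paired right vector flipped with it) so transforms are deterministic
across platforms.

Three modalities are fused by a left-fold cascade of the pairwise
transform in the configured order (default MRI, PET, CSF), recorded in the
provenance so runs are reproducible; each stage caps the retained
dimension at $c-1$, so the final fused dimension is at most $2(c-1)$.

**CCA baseline.** Classical canonical correlation via whitened
cross-covariance SVD with ridge-regularised within-set covariances
(default ridge 1e-3 in the pipeline, since $p = 93 \gtrsim n_{\text{train}}$
in the study conditions makes unregularised CCA ill-posed).

## Evaluation protocol

Binary tasks (the three class pairs) are evaluated with a linear SVM
(C = 1, features standardised per training fold) under stratified
$k$-fold CV (default 10 folds, 10 repeats; fresh fold randomisation per
repeat derived from the seed). Metrics: ACC, SEN, SPE, BAC = (SEN+SPE)/2,
PPV, NPV per fold, aggregated as mean ± SD over all folds, with per-repeat
means also retained; zero-denominator rates are NaN-flagged, never coerced
to 0. ROC/AUC come from the pooled decision scores over all test folds;
the trapezoidal AUC over the empirical curve equals the normalised
Mann–Whitney statistic (verified against brute-force pair counting).

**Leakage control.** Every fitted quantity is learned on the training fold
only. The published forms of the imputers and LRR are transductive, so
out-of-sample extensions were defined: held-out columns are KNN-imputed
against the completed training matrix, EM-imputed from the training-fold
Gaussian, SVD-imputed by least-squares regression on the training low-rank
basis; LRR denoising of a held-out column is projection onto the column
space of the denoised training matrix; DCA/CCA transforms and the scaler/SVM
apply their training-fold parameters unchanged. A clearly-labelled
`leaky` option performs global imputation/denoising before splitting, for
quantifying that bias. Stratified folds are used because the emulated
cohorts have unbalanced class sizes.

`compare_methods` runs named pipelines — `ldf` (KNN K=5 → LRR → DCA),
`knn`/`em`/`svd` (impute-then-concatenate), `cca`, `concat` — with
identical fold assignments per seed, giving a paired design.

## Synthetic study conditions

The generator emulates the shape and correlation structure of the target
cohorts, not their marginals: a `latent_rank`-dimensional standard-normal
latent matrix shared by all modalities, class structure entering through
latent mean shifts (norm = `class_separation`, directions random but
centred), per-modality random loadings, dense Gaussian noise, column-sparse
corruption (whole samples, matching the L2,1 error model), and
exact-count MCAR masking (⌊p·d·n⌋ distinct cells, so missing counts are
deterministic) with an optional whole-modality-block mode mirroring
per-modality subject availability. Defaults: 3 classes × 40 samples,
dims [93, 93, 3], rank 5, separation 1.0, noise SD 0.2.

Because class signal enters through *shared* latent means, cross-modal
correlation is class-discriminative — precisely the structure DCA
exploits. What the generator does **not** emulate: realistic feature
marginals or covariances of imaging data, site/batch effects, informative
(non-random) missingness, label noise. Passing tests therefore demonstrate
the algorithmic properties (recovery, identities, calibration, fusion
benefit) under the stated generative assumptions, not clinical performance.

Problem sizes in the tests and acceptance script (oracle matrices 40×60,
cohort analogues of 100–200 samples, 10×10 or 10×2 CV) were chosen so the
full suite runs in minutes on one CPU while keeping every fold's training
set comfortably larger than the fused dimension.

## Known limitations

* LRR runs per modality independently; no joint/stacked variant.
* The cascade order of three-way DCA is a convention (recorded in
  provenance); different orders give different, equally valid fusions.
* λ for LRR, the SVM kernel/C, and fold stratification are engineering
  defaults — the method family leaves them unspecified — and all are
  exposed as configuration.
* EM imputation is iterated conditional means under a single Gaussian; no
  multiple imputation or uncertainty propagation.
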