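import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldfusion import (
    PipelineSpec,
    SimulationConfig,
    compare_methods,
    confusion_metrics,
    generate,
    repeated_cv,
    roc_auc,
)
from ldfusion.evaluate import FusionPipeline, binary_task


def _preds_from_counts(tp, fn, tn, fp):
    y_true = np.array([1] * (tp + fn) + [0] * (tn + fp))
    y_pred = np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp)
    return y_true, y_pred


class TestConfusionMetrics:
    def test_definitional_values(self):
        m = confusion_metrics(*_preds_from_counts(9, 1, 8, 2), positive_label=1)
        assert m.SEN == pytest.approx(0.90)
        assert m.SPE == pytest.approx(0.80)
        assert m.ACC == pytest.approx(0.85)
        assert m.BAC == pytest.approx(0.85)
        assert m.PPV == pytest.approx(9 / 11)
        assert m.NPV == pytest.approx(8 / 9)
        assert not m.undefined

    def test_perfect_prediction(self):
        m = confusion_metrics(*_preds_from_counts(5, 0, 5, 0), positive_label=1)
        assert all(getattr(m, name) == 1.0 for name in ("ACC", "SEN", "SPE", "BAC", "PPV", "NPV"))

    def test_all_predicted_positive_flags_npv(self):
        m = confusion_metrics(*_preds_from_counts(5, 0, 0, 5), positive_label=1)
        assert m.SPE == 0.0
        assert np.isnan(m.NPV)
        assert "NPV" in m.undefined

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="pairwise"):
            confusion_metrics(np.array([0, 1, 2]), np.array([0, 1, 2]), positive_label=1)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        tp=st.integers(0, 20),
        fn=st.integers(0, 20),
        tn=st.integers(0, 20),
        fp=st.integers(0, 20),
    )
    def test_bac_identity_under_fuzzing(self, tp, fn, tn, fp):
        if tp + fn + tn + fp == 0:
            return
        m = confusion_metrics(*_preds_from_counts(tp, fn, tn, fp), positive_label=1)
        if not np.isnan(m.BAC):
            assert m.BAC == pytest.approx((m.SEN + m.SPE) / 2)
        counts = (m.tp, m.fn, m.tn, m.fp)
        assert counts == (tp, fn, tn, fp)


def _auc_pair_counting(scores, labels, positive):
    """Brute-force Mann-Whitney oracle: fraction of correctly ordered
    positive-negative pairs, ties counting one half."""
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc(np.array([1.0, 2.0, -1.0, -2.0]), np.array([1, 1, 0, 0]), 1)
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        auc, _ = roc_auc(np.zeros(10), np.array([0, 1] * 5), 1)
        assert auc == pytest.approx(0.5)

    def test_worked_example(self):
        auc, _ = roc_auc(
            np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]), 1
        )
        assert auc == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 50)
        scores = np.round(rng.normal(size=n), 1)  # induce ties
        labels = rng.integers(0, 2, size=n)
        if labels.all() or not labels.any():
            labels[0] = 1 - labels[0]
        auc, _ = roc_auc(scores, labels, 1)
        assert auc == pytest.approx(_auc_pair_counting(scores, labels, 1), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.ones(4), 1)


@pytest.fixture(scope="module")
def binary_dataset():
    cfg = SimulationConfig(
        n_per_class=30, n_classes=2, modality_dims=[15, 10, 3], latent_rank=3,
        class_separation=2.0, noise_sd=0.3, missing_frac=0.05, seed=17,
    )
    return generate(cfg)


FAST_SPEC = PipelineSpec(imputer="mean", denoise=False, fusion="dca")


class TestRepeatedCV:
    def test_folds_partition_samples(self, binary_dataset):
        res = repeated_cv(binary_dataset, FAST_SPEC, n_folds=5, n_repeats=2, seed=1)
        n = binary_dataset.n_samples
        for rep in range(2):
            folds = res.fold_indices[rep * 5 : (rep + 1) * 5]
            seen = np.concatenate(folds)
            assert sorted(seen) == list(range(n))
        assert len(res.per_fold) == 10
        assert len(res.repeat_means) == 2

    def test_same_seed_reproduces(self, binary_dataset):
        a = repeated_cv(binary_dataset, FAST_SPEC, n_folds=5, n_repeats=1, seed=3)
        b = repeated_cv(binary_dataset, FAST_SPEC, n_folds=5, n_repeats=1, seed=3)
        assert a.mean == b.mean
        assert a.auc == b.auc
        assert all(np.array_equal(x, y) for x, y in zip(a.fold_indices, b.fold_indices))

    def test_too_many_folds_rejected(self, binary_dataset):
        with pytest.raises(ValueError, match="folds"):
            repeated_cv(binary_dataset, FAST_SPEC, n_folds=40, n_repeats=1, seed=0)

    def test_null_data_chance_level(self):
        """Zero class separation: accuracy stays at chance within the spread
        of the fold distribution."""
        cfg = SimulationConfig(
            n_per_class=50, n_classes=2, modality_dims=[20, 10, 3], latent_rank=3,
            class_separation=0.0, noise_sd=0.3, seed=23,
        )
        ds = generate(cfg)
        res = repeated_cv(ds, FAST_SPEC, n_folds=10, n_repeats=3, seed=2)
        assert abs(res.mean["ACC"] - 0.5) <= 3 * res.sd["ACC"]

    def test_no_leakage_test_labels_cannot_change_fit(self, binary_dataset):
        """Fitted parameters hash identically whether or not test-fold labels
        are permuted — preprocessing never sees the held-out fold."""
        train_idx = np.arange(0, 50)
        test_idx = np.arange(50, binary_dataset.n_samples)
        scrambled = binary_dataset.copy()
        rng = np.random.default_rng(0)
        for m in scrambled.modalities:
            m.values[:, test_idx] = rng.normal(size=(m.n_features, len(test_idx)))
        scrambled.labels[test_idx] = rng.integers(0, 2, size=len(test_idx))
        pipe1 = FusionPipeline(FAST_SPEC).fit(
            binary_dataset.subset(train_idx).modalities, binary_dataset.labels[train_idx]
        )
        pipe2 = FusionPipeline(FAST_SPEC).fit(
            scrambled.subset(train_idx).modalities, scrambled.labels[train_idx]
        )
        assert pipe1.fitted_hash() == pipe2.fitted_hash()

    def test_leaky_variant_runs(self, binary_dataset):
        res = repeated_cv(
            binary_dataset, PipelineSpec(imputer="knn", fusion="dca"),
            n_folds=5, n_repeats=1, seed=0, leaky=True,
        )
        assert 0.0 <= res.mean["ACC"] <= 1.0


class TestCompareMethods:
    def test_unknown_method_lists_valid(self, binary_dataset):
        with pytest.raises(ValueError, match="valid names"):
            compare_methods(binary_dataset, ["nope"], n_folds=3, n_repeats=1)

    def test_paired_folds_across_methods(self, binary_dataset):
        table, results = compare_methods(
            binary_dataset, ["concat", "cca"], n_folds=3, n_repeats=1, seed=5
        )
        (task,) = {t for _, t in results}
        f1 = results[("concat", task)].fold_indices
        f2 = results[("cca", task)].fold_indices
        assert all(np.array_equal(x, y) for x, y in zip(f1, f2))
        assert set(table["method"]) == {"concat", "cca"}

    def test_strongly_separable_all_methods_accurate(self):
        """With a large class effect every pipeline classifies nearly
        perfectly — a smoke check that no stage destroys signal."""
        cfg = SimulationConfig(
            n_per_class=25, n_classes=2, modality_dims=[20, 15, 3], latent_rank=3,
            class_separation=4.0, noise_sd=0.2, missing_frac=0.02, seed=31,
        )
        ds = generate(cfg)
        table, _ = compare_methods(
            ds, ["ldf", "knn", "em", "svd", "cca", "concat"],
            n_folds=5, n_repeats=1, seed=2,
        )
        accs = table[table.metric == "ACC"].set_index("method")["mean"]
        assert (accs > 0.9).all(), accs.to_dict()

    def test_single_modality_task_subset(self, binary_dataset):
        sub = binary_task(binary_dataset, 0, 1)
        assert sub.n_samples == binary_dataset.n_samples

    def test_fusion_recovers_complementary_signal(self):
        """Each modality alone is weakly informative; fused features beat the
        best single modality on AUC (averaged over replicates)."""
        from ldfusion.datasets import MultimodalDataset

        fused_aucs, single_aucs = [], []
        for seed in range(3):
            cfg = SimulationConfig(
                n_per_class=50, n_classes=2, modality_dims=[93, 93, 3], latent_rank=3,
                class_separation=0.5, noise_sd=1.0, seed=100 + seed,
            )
            ds = generate(cfg)
            res = repeated_cv(ds, FAST_SPEC, n_folds=5, n_repeats=1, seed=3)
            fused_aucs.append(res.auc)
            singles = []
            for m in ds.modalities:
                sub = MultimodalDataset([m], ds.labels)
                r = repeated_cv(
                    sub, PipelineSpec(imputer="mean", fusion="concat"),
                    n_folds=5, n_repeats=1, seed=3,
                )
                singles.append(r.auc)
            single_aucs.append(singles)
        mean_fused = np.mean(fused_aucs)
        mean_singles = np.mean(single_aucs, axis=0)
        assert (mean_fused > mean_singles).all(), (mean_fused, mean_singles)
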