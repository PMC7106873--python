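import numpy as np
import pytest

from ldfusion import (
    CCAFuser,
    MultisetDCA,
    between_class_scatter,
    cca_fuse,
    dca_fit,
    dca_transform,
    fuse_multimodal,
    fuse_pair,
    unitize_scatter,
)


def _labelled_sets(seed, p=8, q=5, n_per=20, c=3):
    """Random feature sets with class-shifted means, column-aligned."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(c), n_per)
    n = n_per * c
    shifts_a = rng.normal(size=(p, c))
    shifts_b = rng.normal(size=(q, c))
    a = rng.normal(size=(p, n)) + shifts_a[:, labels]
    b = rng.normal(size=(q, n)) + shifts_b[:, labels]
    return a, b, labels


class TestBetweenClassScatter:
    def test_hand_example(self):
        """Two 1-D-separated classes: grand mean (3,0), class means (1,0) and
        (5,0), sqrt(2)-weighted deviations give S_inter = [[16,0],[0,0]]."""
        a = np.array([[0.0, 2.0, 4.0, 6.0], [0.0, 0.0, 0.0, 0.0]])
        labels = np.array([0, 0, 1, 1])
        phi, s = between_class_scatter(a, labels)
        assert np.allclose(
            np.abs(phi), np.sqrt(2) * np.array([[2.0, 2.0], [0.0, 0.0]])
        )
        assert np.allclose(s, [[16.0, 0.0], [0.0, 0.0]])

    def test_identical_class_means_give_zero(self):
        a = np.array([[1.0, -1.0, 1.0, -1.0], [0.0, 2.0, 0.0, 2.0]])
        labels = np.array([0, 0, 1, 1])
        _, s = between_class_scatter(a, labels)
        assert np.allclose(s, 0.0)

    def test_psd_and_rank_bound(self):
        a, _, labels = _labelled_sets(0)
        _, s = between_class_scatter(a, labels)
        assert np.allclose(s, s.T)
        eig = np.linalg.eigvalsh(s)
        assert eig.min() >= -1e-10
        assert np.sum(eig > 1e-8 * eig.max()) <= len(np.unique(labels)) - 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            between_class_scatter(np.ones((2, 4)), np.zeros(4))


class TestUnitizeScatter:
    def test_two_class_example_unit_scatter(self):
        a = np.array([[0.0, 2.0, 4.0, 6.0], [0.0, 0.0, 0.0, 0.0]])
        phi, s = between_class_scatter(a, np.array([0, 0, 1, 1]))
        w, eig = unitize_scatter(phi)
        assert w.shape[1] == 1
        assert np.allclose(w.T @ s @ w, [[1.0]], atol=1e-10)

    def test_orthogonal_columns_full_rank(self):
        phi = np.array([[2.0, 0.0], [0.0, 2.0], [0.0, 0.0]])
        w, _ = unitize_scatter(phi)
        assert w.shape[1] == 2
        assert np.allclose(w.T @ (phi @ phi.T) @ w, np.eye(2), atol=1e-10)

    def test_scale_invariance(self):
        phi = np.array([[2.0, 0.5], [0.3, 2.0], [0.1, 0.0]])
        w1, _ = unitize_scatter(phi)
        w10, _ = unitize_scatter(10.0 * phi)
        s10 = (10 * phi) @ (10 * phi).T
        assert w1.shape[1] == w10.shape[1]
        assert np.allclose(w10.T @ s10 @ w10, np.eye(w10.shape[1]), atol=1e-10)

    def test_zero_scatter_rejected(self):
        with pytest.raises(ValueError, match="discriminative"):
            unitize_scatter(np.zeros((3, 2)))


class TestDCAFit:
    @pytest.mark.parametrize("seed", range(10))
    def test_algebraic_identities(self, seed):
        """Both defining identities hold on every nondegenerate instance:
        the unitized between-class scatter and the transformed between-class
        cross-covariance equal I_r."""
        a, b, labels = _labelled_sets(seed)
        t = dca_fit(a, b, labels)
        phi_a, s_a = between_class_scatter(a, labels)
        phi_b, _ = between_class_scatter(b, labels)
        assert np.abs(t.W_a @ s_a @ t.W_a.T - np.eye(t.r)).max() <= 1e-10
        cross = (t.W_a @ phi_a) @ (t.W_b @ phi_b).T
        assert np.abs(cross - np.eye(t.r)).max() <= 1e-8
        assert t.r <= len(np.unique(labels)) - 1

    def test_identical_sets(self):
        a, _, labels = _labelled_sets(3)
        t = dca_fit(a, a.copy(), labels)
        phi, _ = between_class_scatter(a, labels)
        cross = (t.W_a @ phi) @ (t.W_b @ phi).T
        assert np.abs(cross - np.eye(t.r)).max() <= 1e-8

    def test_affine_invariance(self):
        """Adding a constant vector to every sample leaves the transform
        unchanged: class-mean deviations cancel the shift."""
        a, b, labels = _labelled_sets(4)
        t0 = dca_fit(a, b, labels)
        t1 = dca_fit(a + np.full((a.shape[0], 1), 7.0), b, labels)
        assert np.allclose(t0.W_a, t1.W_a, atol=1e-8)
        assert np.allclose(t0.W_b, t1.W_b, atol=1e-8)

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            dca_fit(np.ones((2, 5)), np.ones((2, 6)), np.zeros(5))


class TestTransformAndFusion:
    def test_transform_is_columnwise_linear(self):
        a, b, labels = _labelled_sets(5)
        t = dca_fit(a, b, labels)
        astar, bstar = dca_transform(t, a, b)
        a5, b5 = dca_transform(t, a[:, :5], b[:, :5])
        assert np.array_equal(astar[:, :5], a5)
        assert np.array_equal(bstar[:, :5], b5)
        za, zb = dca_transform(t, np.zeros_like(a), np.zeros_like(b))
        assert not za.any() and not zb.any()

    def test_transform_shape_mismatch(self):
        a, b, labels = _labelled_sets(6)
        t = dca_fit(a, b, labels)
        with pytest.raises(ValueError, match="features"):
            dca_transform(t, a[:-1], b)

    def test_fuse_pair_concat_roundtrip(self):
        x = np.arange(3.0).reshape(1, 3)
        y = -x
        fused = fuse_pair(x, y, mode="concat")
        assert fused.values.shape == (2, 3)
        assert np.array_equal(fused.values[:1], x)
        assert np.array_equal(fused.values[1:], y)
        assert np.array_equal(fuse_pair(x, y, mode="sum").values, np.zeros((1, 3)))

    def test_fuse_pair_column_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            fuse_pair(np.ones((1, 3)), np.ones((1, 4)))

    def test_cascade_base_case_equals_pairwise(self):
        a, b, labels = _labelled_sets(7)
        t = dca_fit(a, b, labels)
        astar, bstar = dca_transform(t, a, b)
        direct = fuse_pair(astar, bstar).values
        cascade = fuse_multimodal([a, b], labels).values
        assert np.allclose(direct, cascade, atol=1e-12)

    def test_three_modality_dimension_cap(self):
        """Each cascade stage caps r at c-1, so three sets fuse into at most
        2(c-1) rows regardless of input dimensions."""
        rng = np.random.default_rng(8)
        labels = np.repeat(np.arange(3), 15)
        shifts = [rng.normal(size=(d, 3)) for d in (93, 93, 3)]
        mats = [
            rng.normal(size=(d, 45)) + s[:, labels]
            for d, s in zip((93, 93, 3), shifts)
        ]
        fused = fuse_multimodal(mats, labels)
        assert fused.values.shape[0] <= 2 * (3 - 1)
        assert fused.values.shape[1] == 45

    def test_sample_permutation_equivariance(self):
        a, b, labels = _labelled_sets(9)
        rng = np.random.default_rng(0)
        perm = rng.permutation(a.shape[1])
        f = fuse_multimodal([a, b], labels).values
        fp = fuse_multimodal([a[:, perm], b[:, perm]], labels[perm]).values
        assert np.allclose(f[:, perm], fp, atol=1e-8)

    def test_held_out_transform(self):
        a, b, labels = _labelled_sets(10)
        fuser = MultisetDCA().fit([a[:, :45], b[:, :45]], labels[:45])
        full = fuser.transform([a, b]).values
        held = fuser.transform([a[:, 45:], b[:, 45:]]).values
        assert np.array_equal(full[:, 45:], held)


class TestCCA:
    def test_identical_sets_perfectly_correlated(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=(5, 200))
        _, corr = cca_fuse(a, a.copy(), ridge=1e-6)
        assert corr[0] >= 0.999

    def test_independent_sets_low_correlation(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=(5, 500))
        b = rng.normal(size=(5, 500))
        _, corr = cca_fuse(a, b, ridge=1e-6)
        assert corr.max() < 0.3

    def test_correlations_sorted_in_unit_interval(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=(6, 80))
        b = 0.5 * a[:4] + rng.normal(size=(4, 80))
        _, corr = cca_fuse(a, b)
        assert np.all(np.diff(corr) <= 1e-12)
        assert np.all((corr >= 0) & (corr <= 1))

    def test_ill_conditioned_requires_ridge(self):
        rng = np.random.default_rng(14)
        base = rng.normal(size=(2, 40))
        a = np.vstack([base, base, base])  # rank-deficient within-set covariance
        b = rng.normal(size=(3, 40))
        with pytest.raises(ValueError, match="ridge"):
            CCAFuser(ridge=0.0).fit([a, b])
        CCAFuser(ridge=1e-3).fit([a, b])  # regularised fit succeeds

    def test_held_out_transform_matches(self):
        rng = np.random.default_rng(15)
        a = rng.normal(size=(4, 60))
        b = rng.normal(size=(3, 60))
        fuser = CCAFuser(ridge=1e-6).fit([a[:, :40], b[:, :40]])
        full = fuser.transform([a, b]).values
        held = fuser.transform([a[:, 40:], b[:, 40:]]).values
        assert np.allclose(full[:, 40:], held)
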