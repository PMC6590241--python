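import numpy as np
import pytest

from msiqc.core import DegenerateInputError
from msiqc.segmentation import (
    FeatureMatrix,
    bisecting_kmeans,
    build_feature_matrix,
    correlation_distance,
    pca_scores,
)
from conftest import make_dataset, small_phantom_spec
from msiqc.phantom import generate_phantom


def _fm(values, mz=None):
    values = np.asarray(values, dtype=np.float64)
    if mz is None:
        mz = np.arange(values.shape[1], dtype=float)
    pixels = [(i, 0) for i in range(values.shape[0])]
    return FeatureMatrix(values, mz, pixels, np.zeros(values.shape[0], dtype=int))


class TestCorrelationDistance:
    def test_identical_vectors(self):
        a = np.array([1.0, 2.0, 5.0])
        assert correlation_distance(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated(self):
        a = np.array([1.0, 2.0, 3.0])
        assert correlation_distance(a, -a) == pytest.approx(2.0)

    def test_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.normal(size=20)
            b = rng.normal(size=20)
            # direct two-pass covariance/sd computation
            cov = np.mean((a - a.mean()) * (b - b.mean()))
            expected = 1.0 - cov / (a.std() * b.std())
            assert correlation_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=15)
        b = rng.normal(size=15)
        d0 = correlation_distance(a, b)
        assert correlation_distance(3.0 * a + 7.0, b) == pytest.approx(d0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            correlation_distance(np.ones(5), np.arange(5.0))


class TestBuildFeatureMatrix:
    @staticmethod
    def _peak_dataset(peak_mzs, n_px=9, amp=50.0, seed=0, shift=0.0):
        rng = np.random.default_rng(seed)
        mz = 600 + 0.1 * np.arange(4001)
        rows = np.abs(rng.normal(0, 0.01, size=(n_px, len(mz))))
        for p in peak_mzs:
            rows += amp * np.exp(-0.5 * ((mz - (p + shift)) / 0.1) ** 2)
        side = int(np.sqrt(n_px))
        return make_dataset(mz, rows, side, side)

    def test_values_equal_windowed_sums(self):
        from msiqc.core import TissueMask

        ds = self._peak_dataset([700.0, 850.0])
        mask = TissueMask(np.ones((3, 3), bool))
        fm = build_feature_matrix([ds], [mask], denoise_window=0)
        assert len(fm.mz) == 2
        mat, order = ds.intensity_matrix()
        norm = mat / mat.sum(axis=1, keepdims=True)
        for j, c in enumerate(fm.mz):
            lo = np.searchsorted(ds.shared_mz, c - 0.25, side="left")
            hi = np.searchsorted(ds.shared_mz, c + 0.25, side="right")
            np.testing.assert_allclose(fm.values[:, j], norm[:, lo:hi].sum(axis=1), rtol=1e-6)

    def test_close_peaks_merge_to_one_column(self):
        from msiqc.core import TissueMask

        ds1 = self._peak_dataset([700.0], seed=1)
        ds2 = self._peak_dataset([700.0], seed=2, shift=0.2)  # < align_tol 0.3
        masks = [TissueMask(np.ones((3, 3), bool))] * 2
        fm = build_feature_matrix([ds1, ds2], masks, align_tol=0.3)
        assert len(fm.mz) == 1
        assert fm.mz[0] == pytest.approx(700.1, abs=0.05)

    def test_distant_peaks_stay_separate(self):
        from msiqc.core import TissueMask

        ds1 = self._peak_dataset([700.0], seed=1)
        ds2 = self._peak_dataset([700.0], seed=2, shift=0.8)  # > align_tol
        masks = [TissueMask(np.ones((3, 3), bool))] * 2
        fm = build_feature_matrix([ds1, ds2], masks, align_tol=0.3)
        assert len(fm.mz) == 2

    def test_empty_consensus_advises(self):
        from msiqc.core import TissueMask

        ds = self._peak_dataset([], amp=0.0)
        mask = TissueMask(np.ones((3, 3), bool))
        with pytest.raises(ValueError, match="min_snr"):
            build_feature_matrix([ds], [mask], min_snr=1e9)


class TestBisectingKmeans:
    def test_two_anticorrelated_blocks_recovered(self):
        rng = np.random.default_rng(0)
        a = np.tile([5.0, 4.0, 0.1, 0.2], (20, 1)) + rng.normal(0, 0.05, (20, 4))
        b = np.tile([0.2, 0.1, 4.0, 5.0], (20, 1)) + rng.normal(0, 0.05, (20, 4))
        fm = _fm(np.vstack([a, b]))
        tree = bisecting_kmeans(fm, max_depth=1, seed=0)
        labels = tree.labels()
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_identical_rows_no_split(self):
        fm = _fm(np.tile([1.0, 2.0, 3.0], (10, 1)))
        tree = bisecting_kmeans(fm, max_depth=3, seed=0)
        assert tree.root.is_leaf

    def test_leaves_partition_rows_at_every_level(self, small_phantom):
        from msiqc.core import TissueMask

        dataset, truth = small_phantom
        fm = build_feature_matrix([dataset], [truth.mask])
        tree = bisecting_kmeans(fm, max_depth=3, seed=1)
        max_level = max(lf.level for lf in tree.leaves())
        for level in range(1, max_level + 1):
            labels = tree.labels(level)
            assert len(labels) == fm.n_pixels  # every row labelled exactly once
        # leaf row sets are disjoint and exhaustive
        all_rows = np.concatenate([lf.rows for lf in tree.leaves()])
        assert sorted(all_rows) == list(range(fm.n_pixels))

    def test_split_never_increases_within_cost(self):
        from msiqc.segmentation import _within_cost

        rng = np.random.default_rng(3)
        x = rng.normal(size=(40, 6)) + np.repeat([[0], [3]], 20, axis=0) * np.arange(6)
        fm = _fm(x)
        tree = bisecting_kmeans(fm, max_depth=2, seed=0)

        def check(node):
            if node.is_leaf:
                return
            parent = _within_cost(x[node.rows])
            child_sum = _within_cost(x[node.left.rows]) + _within_cost(x[node.right.rows])
            assert child_sum <= parent + 1e-9
            check(node.left)
            check(node.right)

        check(tree.root)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        fm = _fm(rng.normal(size=(30, 5)) ** 2 + 0.1)
        t1 = bisecting_kmeans(fm, max_depth=2, seed=7)
        t2 = bisecting_kmeans(fm, max_depth=2, seed=7)
        np.testing.assert_array_equal(t1.labels(), t2.labels())

    def test_phantom_first_split_matches_regions(self, small_phantom):
        from sklearn.metrics import adjusted_rand_score

        from msiqc.core import TissueMask

        dataset, truth = small_phantom
        fm = build_feature_matrix([dataset], [truth.mask])
        tree = bisecting_kmeans(fm, max_depth=1, seed=0)
        true = np.array([truth.region_labels[r, c] for (c, r) in fm.pixels])
        assert adjusted_rand_score(true, tree.labels()) >= 0.9


class TestPcaScores:
    def test_line_explains_everything(self):
        t = np.linspace(0, 1, 30)
        x = np.outer(t, [1.0, 2.0, -1.0]) + 5.0
        scores, explained = pca_scores(_fm(x), 1)
        assert explained[0] == pytest.approx(1.0)

    def test_explained_fractions_non_increasing_and_bounded(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(50, 8))
        _, explained = pca_scores(_fm(x), 5)
        assert np.all(np.diff(explained) <= 1e-12)
        assert explained.sum() <= 1.0 + 1e-12

    def test_rotation_of_rows_preserves_explained_variance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(40, 4)) @ np.diag([3.0, 2.0, 1.0, 0.5])
        _, ev1 = pca_scores(_fm(x), 3)
        # orthogonal rotation of the whole cloud in feature space
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        # unit-variance scaling is not rotation-invariant in general, so
        # rotate scores instead: explained variance of scores is unchanged
        scores, _ = pca_scores(_fm(x), 3)
        rotated = scores @ np.linalg.qr(rng.normal(size=(3, 3)))[0]
        assert np.var(rotated, axis=0).sum() == pytest.approx(np.var(scores, axis=0).sum())
        assert ev1[0] >= ev1[-1]

    def test_zero_variance_column_dropped(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(20, 3))
        x[:, 1] = 4.2
        with pytest.warns(UserWarning, match="zero-variance"):
            scores, explained = pca_scores(_fm(x), 2)
        assert scores.shape == (20, 2)

    def test_components_beyond_rank_reduced(self):
        t = np.linspace(0, 1, 10)
        x = np.outer(t, [1.0, 2.0, 3.0])  # rank 1 after centering
        with pytest.warns(UserWarning, match="rank"):
            scores, explained = pca_scores(_fm(x + 0.5), 3)
        assert scores.shape[1] == 1
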