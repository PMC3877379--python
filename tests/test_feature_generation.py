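import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from patreg.feature_generation import (
    CONNECTIVITY_26,
    CorrelationVolume,
    FeatureMatrix,
    RankingConfig,
    correlation_volume,
    extract_features,
    rank_and_select,
    watershed_cluster,
)
from patreg.imaging_io import BrainMask, BrainVolume, VolumeGrid


def _volumes_from_stack(stack, grid):
    return [BrainVolume(grid=grid, data=s, modality="GM") for s in stack]


class TestCorrelationVolume:
    def test_voxel_equal_to_score_gives_r_one(self, grid16, ball_mask):
        scores = np.array([0.0, 1.0, 2.0, 5.0, -1.0])
        vox = tuple(np.argwhere(ball_mask.data)[0])
        stack = np.zeros((5,) + grid16.shape)
        for i, s in enumerate(scores):
            stack[i][vox] = s
        cv = correlation_volume(_volumes_from_stack(stack, grid16), scores, ball_mask)
        assert cv.data[vox] == pytest.approx(1.0)

    def test_anticorrelated_voxel_gives_minus_one(self, grid16, ball_mask):
        scores = np.array([0.0, 1.0, 2.0, 3.0])
        vox = tuple(np.argwhere(ball_mask.data)[3])
        stack = np.zeros((4,) + grid16.shape)
        for i, s in enumerate(scores):
            stack[i][vox] = -2.0 * s + 7.0
        cv = correlation_volume(_volumes_from_stack(stack, grid16), scores, ball_mask)
        assert cv.data[vox] == pytest.approx(-1.0)

    def test_constant_voxels_get_zero(self, grid16, ball_mask):
        scores = np.array([1.0, 2.0, 3.0])
        stack = np.ones((3,) + grid16.shape)  # every voxel constant
        cv = correlation_volume(_volumes_from_stack(stack, grid16), scores, ball_mask)
        assert np.all(cv.data == 0)

    def test_outside_mask_is_zero(self, grid16, ball_mask, rng):
        scores = rng.standard_normal(6)
        stack = rng.standard_normal((6,) + grid16.shape)
        cv = correlation_volume(_volumes_from_stack(stack, grid16), scores, ball_mask)
        assert np.all(cv.data[~ball_mask.data] == 0)
        assert np.all(np.abs(cv.data) <= 1.0)

    def test_matches_scipy_pearsonr(self, grid16, ball_mask, rng):
        from scipy import stats
        scores = rng.standard_normal(8)
        stack = rng.standard_normal((8,) + grid16.shape)
        cv = correlation_volume(_volumes_from_stack(stack, grid16), scores, ball_mask)
        for vox in map(tuple, np.argwhere(ball_mask.data)[::200]):
            expected = stats.pearsonr(stack[(slice(None),) + vox], scores).statistic
            assert cv.data[vox] == pytest.approx(expected, abs=1e-12)

    def test_rejects_degenerate_inputs(self, grid16, ball_mask, rng):
        stack = rng.standard_normal((2,) + grid16.shape)
        with pytest.raises(ValueError, match="at least 3"):
            correlation_volume(_volumes_from_stack(stack, grid16),
                               np.array([1.0, 2.0]), ball_mask)
        stack = rng.standard_normal((3,) + grid16.shape)
        with pytest.raises(ValueError, match="zero variance"):
            correlation_volume(_volumes_from_stack(stack, grid16),
                               np.array([1.0, 1.0, 1.0]), ball_mask)
        with pytest.raises(ValueError, match="volumes but"):
            correlation_volume(_volumes_from_stack(stack, grid16),
                               np.array([1.0, 2.0]), ball_mask)


def _bump(shape, center, width=2.0):
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return np.exp(-d2 / (2 * width**2))


class TestWatershed:
    def test_uniform_magnitude_single_cluster(self, grid16, ball_mask):
        cv = CorrelationVolume(grid=grid16, data=np.where(ball_mask.data, 0.5, 0.0))
        atlas = watershed_cluster(cv, ball_mask, min_cluster_voxels=5,
                                  pre_smooth_fwhm=0.0)
        assert atlas.n_clusters == 1
        assert (atlas.labels[ball_mask.data] == 1).all()

    def test_two_bumps_two_clusters_with_peak_membership(self, grid16, ball_mask):
        c1, c2 = (5, 8, 8), (11, 8, 8)
        data = 0.8 * _bump(grid16.shape, c1) + 0.6 * _bump(grid16.shape, c2)
        cv = CorrelationVolume(grid=grid16, data=np.where(ball_mask.data, data, 0.0))
        atlas = watershed_cluster(cv, ball_mask, min_cluster_voxels=5,
                                  pre_smooth_fwhm=0.0)
        assert atlas.n_clusters == 2
        assert atlas.labels[c1] != atlas.labels[c2]
        assert atlas.labels[c1] > 0 and atlas.labels[c2] > 0

    def test_labels_partition_mask(self, grid16, ball_mask, rng):
        data = np.where(ball_mask.data, rng.random(grid16.shape), 0.0)
        cv = CorrelationVolume(grid=grid16, data=data)
        atlas = watershed_cluster(cv, ball_mask, min_cluster_voxels=10)
        assert np.all(atlas.labels[ball_mask.data] > 0)
        assert np.all(atlas.labels[~ball_mask.data] == 0)
        labs = np.unique(atlas.labels[ball_mask.data])
        assert list(labs) == list(range(1, len(labs) + 1))
        assert int(atlas.table["n_voxels"].sum()) == int(ball_mask.data.sum())

    def test_clusters_26_connected_random_fixtures(self, grid16, ball_mask):
        # independent oracle: scipy.ndimage.label with full connectivity must
        # see each cluster as exactly one component
        rng = np.random.default_rng(4242)
        for trial in range(20):
            data = np.where(ball_mask.data, rng.random(grid16.shape), 0.0)
            cv = CorrelationVolume(grid=grid16, data=data)
            atlas = watershed_cluster(cv, ball_mask, min_cluster_voxels=8,
                                      pre_smooth_fwhm=2.0 if trial % 2 else 0.0)
            for lab in atlas.cluster_labels():
                _, n_comp = ndimage.label(atlas.labels == lab,
                                          structure=CONNECTIVITY_26)
                assert n_comp == 1, f"cluster {lab} split into {n_comp} parts"

    def test_min_cluster_size_enforced(self, grid16, ball_mask):
        rng = np.random.default_rng(7)
        data = np.where(ball_mask.data, rng.random(grid16.shape), 0.0)
        cv = CorrelationVolume(grid=grid16, data=data)
        atlas = watershed_cluster(cv, ball_mask, min_cluster_voxels=30,
                                  pre_smooth_fwhm=0.0)
        assert (atlas.table["n_voxels"] >= 30).all()

    def test_isolated_small_component_survives(self, grid16):
        # a mask with a 2-voxel island far from the main ball cannot merge
        mask_data = np.zeros(grid16.shape, dtype=bool)
        mask_data[4:9, 4:9, 4:9] = True
        mask_data[14, 14, 14] = True
        mask_data[14, 14, 15] = True
        mask = BrainMask(grid=grid16, data=mask_data)
        cv = CorrelationVolume(grid=grid16, data=np.where(mask_data, 0.3, 0.0))
        atlas = watershed_cluster(cv, mask, min_cluster_voxels=10,
                                  pre_smooth_fwhm=0.0)
        assert np.all(atlas.labels[mask_data] > 0)
        assert 2 in atlas.table["n_voxels"].to_numpy()

    def test_deterministic(self, grid16, ball_mask):
        rng = np.random.default_rng(99)
        data = np.where(ball_mask.data, rng.random(grid16.shape), 0.0)
        cv = CorrelationVolume(grid=grid16, data=data)
        a = watershed_cluster(cv, ball_mask, min_cluster_voxels=10)
        b = watershed_cluster(cv, ball_mask, min_cluster_voxels=10)
        np.testing.assert_array_equal(a.labels, b.labels)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_empty_mask_rejected_at_construction(self, grid16):
        with pytest.raises(ValueError, match="at least one voxel"):
            BrainMask(grid=grid16, data=np.zeros(grid16.shape, dtype=bool))


class TestExtractFeatures:
    def test_cluster_means_by_hand(self, grid16, ball_mask):
        cv = CorrelationVolume(grid=grid16, data=np.where(ball_mask.data, 1.0, 0.0))
        atlas = watershed_cluster(cv, ball_mask, min_cluster_voxels=1,
                                  pre_smooth_fwhm=0.0, modality="WM")
        vol_data = np.zeros(grid16.shape)
        vol_data[ball_mask.data] = 3.5
        vols = [BrainVolume(grid=grid16, data=vol_data, modality="WM")]
        fm = extract_features(atlas, vols, subject_ids=["s0"])
        assert fm.values.shape == (1, atlas.n_clusters)
        np.testing.assert_allclose(fm.values, 3.5)
        assert fm.columns[0] == ("WM", 1)

    def test_matches_manual_masked_mean(self, grid16, ball_mask, rng):
        data = np.where(ball_mask.data, rng.random(grid16.shape), 0.0)
        atlas = watershed_cluster(CorrelationVolume(grid=grid16, data=data),
                                  ball_mask, min_cluster_voxels=10)
        vol = rng.standard_normal(grid16.shape)
        fm = extract_features(atlas, [BrainVolume(grid=grid16, data=vol)])
        for j, (_, lab) in enumerate(fm.columns):
            assert fm.values[0, j] == pytest.approx(vol[atlas.labels == lab].mean())


class TestFeatureMatrix:
    def test_duplicate_provenance_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            FeatureMatrix(values=np.zeros((2, 2)),
                          columns=[("GM", 1), ("GM", 1)])

    def test_concat_preserves_order_and_provenance(self, rng):
        a = FeatureMatrix(values=rng.random((3, 2)), columns=[("GM", 1), ("GM", 2)])
        b = FeatureMatrix(values=rng.random((3, 1)), columns=[("PET", 1)])
        c = FeatureMatrix.concat([a, b])
        assert c.columns == [("GM", 1), ("GM", 2), ("PET", 1)]
        np.testing.assert_array_equal(c.values[:, :2], a.values)

    def test_subset_roundtrip(self, rng):
        fm = FeatureMatrix(values=rng.random((4, 3)),
                           columns=[("GM", 1), ("WM", 1), ("PET", 2)])
        sub = fm.subset([2, 0])
        assert sub.columns == [("PET", 2), ("GM", 1)]
        np.testing.assert_array_equal(sub.values[:, 1], fm.values[:, 0])


class TestRankAndSelect:
    def test_orders_by_correlation_power(self, rng):
        n = 40
        y = rng.standard_normal(n)
        X = np.column_stack([
            rng.standard_normal(n),          # noise
            y + 0.1 * rng.standard_normal(n),  # strong +
            -y + 0.5 * rng.standard_normal(n),  # medium -
        ])
        fm = FeatureMatrix(values=X, columns=[("GM", 1), ("GM", 2), ("GM", 3)])
        order = rank_and_select(fm, y, RankingConfig(), k_left_out=4)
        assert order[0] == 1
        assert order[1] == 2

    def test_cap_arithmetic_default_cohort_scale(self):
        # N_c = 80, k_c = round(0.1*80) = 8 -> cap = 3 * 72 = 216
        assert RankingConfig(multiplier=3).cap(80, 8) == 216

    def test_truncates_to_cap(self, rng):
        n, f = 10, 30
        y = rng.standard_normal(n)
        fm = FeatureMatrix(values=rng.standard_normal((n, f)),
                           columns=[("GM", i) for i in range(f)])
        sel = rank_and_select(fm, y, RankingConfig(multiplier=2),
                              k_left_out=1, n_subjects=n + 1)
        assert len(sel) == 2 * n  # 2 * (11 - 1) = 20 < 30

    def test_f_max_ceiling(self, rng):
        n, f = 20, 30
        y = rng.standard_normal(n)
        fm = FeatureMatrix(values=rng.standard_normal((n, f)),
                           columns=[("GM", i) for i in range(f)])
        sel = rank_and_select(fm, y, RankingConfig(), k_left_out=2, f_max=7)
        assert len(sel) == 7

    def test_tie_break_modality_then_label(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        col = y.copy()  # identical |r| = 1 for all
        fm = FeatureMatrix(
            values=np.column_stack([col, col, col]),
            columns=[("PET", 1), ("GM", 2), ("GM", 1)],
        )
        order = rank_and_select(fm, y, RankingConfig(), k_left_out=1)
        assert [fm.columns[i] for i in order] == [("GM", 1), ("GM", 2), ("PET", 1)]

    def test_zero_variance_scores_rejected(self, rng):
        fm = FeatureMatrix(values=rng.random((4, 2)),
                           columns=[("GM", 1), ("GM", 2)])
        with pytest.raises(ValueError, match="zero variance"):
            rank_and_select(fm, np.ones(4), RankingConfig(), k_left_out=1)
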