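"""Segmentation, engineered features, NC-ROI and active learning."""

import numpy as np
import pytest
from scipy.linalg import eigh

from lamikit import cellid


def two_blob_candidate():
    """Two 5-voxel line blobs 10 um apart with orthogonal spectra."""
    vox = np.array([[0, 5, k] for k in range(5)] + [[0, 5, k + 15] for k in range(5)])
    vol = np.zeros((2, 1, 11, 25))
    for k in range(5):
        vol[0, 0, 5, k] = 10.0      # blob A emits in channel 0
        vol[1, 0, 5, 15 + k] = 10.0  # blob B emits in channel 1
    return cellid.CandidateRegion(voxels=vox), vol


class TestSegmentation:
    def test_two_separated_blobs_two_regions(self):
        zz, yy, xx = np.indices((8, 40, 40)).astype(float)
        v = np.exp(-(((zz - 4) / 1.5) ** 2 + ((yy - 10) / 3) ** 2 + ((xx - 10) / 3) ** 2))
        v += np.exp(-(((zz - 4) / 1.5) ** 2 + ((yy - 28) / 3) ** 2 + ((xx - 28) / 3) ** 2))
        regions = cellid.segment_candidates(
            v, cellid.SegParams(smoothing_sigma=2, background_radius=15, threshold=0.05, seed_size=8),
            spacing=(4, 1, 1),
        )
        assert len(regions) == 2

    def test_dumbbell_split_by_seeds(self):
        zz, yy, xx = np.indices((6, 20, 48)).astype(float)
        v = np.exp(-(((zz - 3) / 1.5) ** 2 + ((yy - 10) / 4) ** 2 + ((xx - 14) / 4) ** 2))
        v += np.exp(-(((zz - 3) / 1.5) ** 2 + ((yy - 10) / 4) ** 2 + ((xx - 34) / 4) ** 2))
        v += 0.25 * np.exp(-(((zz - 3) / 1.5) ** 2 + ((yy - 10) / 4) ** 2 + ((xx - 24) / 8) ** 2))
        regions = cellid.segment_candidates(
            v, cellid.SegParams(smoothing_sigma=1.5, background_radius=20, threshold=0.05, seed_size=10),
            spacing=(4, 1, 1),
        )
        assert len(regions) == 2

    def test_empty_volume_yields_no_regions(self):
        assert cellid.segment_candidates(np.zeros((4, 10, 10))) == []

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 1, (5, 24, 24))
        p = cellid.SegParams(smoothing_sigma=1.5, background_radius=8, threshold=0.08, seed_size=4)
        a = cellid.segment_candidates(v, p)
        b = cellid.segment_candidates(v, p)
        assert len(a) == len(b)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.voxels, rb.voxels)


class TestEngineerFeatures:
    def test_spectral_normalization_arithmetic(self):
        vox = np.array([[0, 0, 0]])
        vol = np.zeros((6, 1, 1, 1))
        vol[:, 0, 0, 0] = [3, 1, 1, 1, 1, 1]
        f = cellid.engineer_features(cellid.CandidateRegion(vox), vol, np.ones(6))
        names = cellid.engineer_feature_names(6)
        spec = f[: 6]
        assert np.allclose(spec, [1, 0, 0, 0, 0, 0])
        assert f[names.index("spec_magnitude")] == pytest.approx(2.0)

    def test_identical_channels_correlate_and_coincide(self):
        rng = np.random.default_rng(0)
        vox = np.argwhere(np.ones((2, 3, 3), dtype=bool))
        data = rng.uniform(1, 5, (1, 2, 3, 3))
        vol = np.concatenate([data, data], axis=0)
        f = cellid.engineer_features(cellid.CandidateRegion(vox), vol, np.zeros(2))
        names = cellid.engineer_feature_names(2)
        assert f[names.index("corr_0_1")] == pytest.approx(1.0)
        assert f[names.index("com_dist_0_1")] == pytest.approx(0.0, abs=1e-12)

    def test_offset_fluorophores_separate_center_of_mass(self):
        """Blobs offset by 4 um in different channels give a 4 um COM split."""
        vol = np.zeros((2, 1, 9, 13))
        vol[0, 0, 4, 2:5] = [1.0, 2.0, 1.0]   # channel 0 centered at x=3 um
        vol[1, 0, 4, 6:9] = [1.0, 2.0, 1.0]   # channel 1 centered at x=7 um
        vox = np.argwhere(vol.sum(axis=0) > 0)
        f = cellid.engineer_features(cellid.CandidateRegion(vox), vol, np.zeros(2), spacing=(4, 1, 1))
        names = cellid.engineer_feature_names(2)
        assert f[names.index("com_dist_0_1")] == pytest.approx(4.0, abs=0.5)

    def test_zero_spectrum_flagged(self):
        vox = np.array([[0, 0, 0]])
        vol = np.ones((3, 1, 1, 1))
        f = cellid.engineer_features(cellid.CandidateRegion(vox), vol, np.ones(3))
        names = cellid.engineer_feature_names(3)
        assert f[names.index("zero_spectrum_flag")] == 1.0
        assert np.allclose(f[:3], 0.0)

    def test_correlations_bounded(self):
        rng = np.random.default_rng(1)
        vox = np.argwhere(np.ones((3, 4, 4), dtype=bool))
        vol = rng.uniform(0, 10, (6, 3, 4, 4))
        f = cellid.engineer_features(cellid.CandidateRegion(vox), vol, np.zeros(6))
        names = cellid.engineer_feature_names(6)
        corr = [f[i] for i, n in enumerate(names) if n.startswith("corr_")]
        assert np.all(np.abs(corr) <= 1.0 + 1e-12)


def brute_force_ncut_bipartition(W):
    """Normalized-cut 2-way split by the second eigenvector of the symmetric
    normalized Laplacian (sign split) — independent oracle for tiny graphs."""
    d = W.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    lsym = np.eye(len(W)) - dinv[:, None] * W * dinv[None, :]
    vals, vecs = eigh(lsym)
    fiedler = vecs[:, 1] * dinv  # back to the random-walk eigenvector
    return fiedler >= 0


class TestNcRoi:
    def test_orthogonal_blobs_returned_pure(self):
        region, vol = two_blob_candidate()
        roi = cellid.nc_roi(region, vol, np.array([1.0, 0.0]), spacing=(4, 1, 1))
        expect = set((0, 5, k) for k in range(5))
        assert set(map(tuple, roi)) == expect

    def test_matches_brute_force_eigendecomposition(self):
        region, vol = two_blob_candidate()
        intens = vol[:, region.voxels[:, 0], region.voxels[:, 1], region.voxels[:, 2]].T
        unit = intens / np.linalg.norm(intens, axis=1, keepdims=True)
        pos = region.voxels * np.array([4.0, 1.0, 1.0])
        W = cellid.nc_adjacency(pos, unit, cellid.NcConfig())
        side = brute_force_ncut_bipartition(W)
        groups = [set(map(tuple, region.voxels[side])), set(map(tuple, region.voxels[~side]))]
        roi = set(map(tuple, cellid.nc_roi(region, vol, np.array([1.0, 0.0]), spacing=(4, 1, 1))))
        assert roi in groups

    def test_alpha_zero_ignores_positions(self):
        region, vol = two_blob_candidate()
        cfg = cellid.NcConfig(alpha=0.0)
        roi_a = set(map(tuple, cellid.nc_roi(region, vol, np.array([1.0, 0.0]), cfg, spacing=(4, 1, 1))))
        # scramble voxel positions (permute rows) without touching spectra
        perm = np.random.default_rng(0).permutation(len(region.voxels))
        region2 = cellid.CandidateRegion(voxels=region.voxels[perm])
        roi_b = set(map(tuple, cellid.nc_roi(region2, vol, np.array([1.0, 0.0]), cfg, spacing=(4, 1, 1))))
        assert roi_a == roi_b

    def test_uniform_spectrum_partition_covers_region(self):
        vox = np.argwhere(np.ones((1, 2, 6), dtype=bool))
        vol = np.ones((2, 1, 2, 6))
        region = cellid.CandidateRegion(vox)
        roi = cellid.nc_roi(region, vol, np.array([1.0, 1.0]), spacing=(4, 1, 1))
        assert 0 < len(roi) <= len(vox)
        assert set(map(tuple, roi)) <= set(map(tuple, vox))

    def test_global_intensity_rescaling_invariant(self):
        region, vol = two_blob_candidate()
        roi_a = set(map(tuple, cellid.nc_roi(region, vol, np.array([1.0, 0.0]), spacing=(4, 1, 1))))
        roi_b = set(map(tuple, cellid.nc_roi(region, 7.5 * vol, np.array([1.0, 0.0]), spacing=(4, 1, 1))))
        assert roi_a == roi_b

    def test_region_smaller_than_clusters_rejected(self):
        region = cellid.CandidateRegion(np.array([[0, 0, 0]]))
        with pytest.raises(ValueError, match="smaller"):
            cellid.nc_roi(region, np.ones((2, 1, 1, 1)), np.array([1.0, 0.0]))

    def test_literal_formula_flag_changes_adjacency(self):
        region, vol = two_blob_candidate()
        intens = vol[:, region.voxels[:, 0], region.voxels[:, 1], region.voxels[:, 2]].T
        unit = intens / np.linalg.norm(intens, axis=1, keepdims=True)
        pos = region.voxels * np.array([4.0, 1.0, 1.0])
        w_fixed = cellid.nc_adjacency(pos, unit, cellid.NcConfig())
        w_literal = cellid.nc_adjacency(pos, unit, cellid.NcConfig(literal_formula=True))
        # under the corrected form, same-spectrum neighbors are more adjacent
        # than orthogonal-spectrum pairs at equal distance; the literal
        # (raw dot-product) form reverses this
        same = (0, 1)       # both in blob A
        cross = (0, 9)      # far pair, orthogonal spectra
        assert w_fixed[same] > w_fixed[cross]
        assert w_literal[same[0], same[1]] < np.exp(-cellid.NcConfig().alpha * 1.0**2) + 1e-12


class TestClassifierAndSelection:
    def test_separable_toy_set_perfect_holdout(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-2, 0.3, (60, 2)), rng.normal(2, 0.3, (60, 2))])
        y = np.r_[np.zeros(60), np.ones(60)].astype(int)
        train = np.r_[0:40, 60:100]
        test = np.r_[40:60, 100:120]
        clf = cellid.EnsembleClassifier(seed=0).fit(X[train], y[train])
        assert np.mean(clf.predict(X[test]) == y[test]) == 1.0

    def test_conflicting_duplicates_score_near_half(self):
        X = np.tile([[1.0, 1.0]], (40, 1))
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        clf = cellid.EnsembleClassifier(seed=0).fit(X, y)
        assert clf.scores(X[:1])[0] == pytest.approx(0.5, abs=0.1)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            cellid.EnsembleClassifier().fit(np.zeros((5, 2)), np.zeros(5))

    def test_ensemble_of_identical_members_equals_member(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (50, 3))
        y = (X[:, 0] > 0).astype(int)
        one = cellid.EnsembleClassifier(n_members=1, seed=5).fit(X, y)
        s1 = one.scores(X)
        stack = np.mean([s1, s1, s1], axis=0)
        assert np.allclose(stack, s1)

    @pytest.mark.parametrize(
        "scores,expect",
        [([0.1, 0.45, 0.9], 1), ([0.5, 0.5, 0.5], 0), ([0.77], 0)],
    )
    def test_uncertainty_selection_rule(self, scores, expect):
        assert cellid.uncertainty_select(np.array(scores)) == expect

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cellid.uncertainty_select(np.array([]))


class TestLabelingSimulation:
    def test_separable_pool_reaches_perfection_with_few_labels(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-2, 0.3, (180, 3)), rng.normal(2, 0.3, (20, 3))])
        y = np.r_[np.zeros(180), np.ones(20)].astype(int)
        curve = cellid.simulate_labeling_experiment(X, y, "uncertainty", max_labels=20, seed=0)
        reached = curve[curve["accuracy"] >= 0.999]
        assert len(reached) > 0
        assert reached["n_labels"].iloc[0] <= 20  # <= 10% of the pool

    def test_random_strategy_positive_rate_matches_prevalence(self):
        X, y = cellid.make_candidate_pool(2000, 0.01, seed=3)
        hits = []
        for seed in range(4):
            rng = np.random.default_rng(seed)
            picks = rng.choice(len(y), 150, replace=False)
            hits.append(y[picks].sum())
        # expected 1.5 positives per 150 random labels at 1% prevalence
        assert np.mean(hits) < 8

    def test_curves_share_seeded_start(self):
        X, y = cellid.make_candidate_pool(500, 0.05, seed=1)
        a = cellid.simulate_labeling_experiment(X, y, "uncertainty", max_labels=4, seed=9)
        b = cellid.simulate_labeling_experiment(X, y, "random", max_labels=4, seed=9)
        assert a["n_labels"].iloc[0] == b["n_labels"].iloc[0] == 2
        assert a["balanced_accuracy"].iloc[0] == pytest.approx(b["balanced_accuracy"].iloc[0])

    def test_unknown_strategy_rejected(self):
        X, y = cellid.make_candidate_pool(100, 0.05, seed=0)
        with pytest.raises(ValueError, match="strategy"):
            cellid.simulate_labeling_experiment(X, y, "oracle")
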