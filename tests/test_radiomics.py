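import numpy as np
import pytest
import pywt

from gliomune.radiomics import (
    discretize,
    extract_feature_vector,
    firstorder_features,
    haar_subbands,
    resample_isotropic,
    shape_features,
    texture_features,
)
from gliomune.radiomics.texture import (
    _glcm_features_single,
    direction_offsets_13,
    glcm_matrix,
    glrlm_matrix,
    glszm_matrix,
)
from gliomune.radiomics.wavelet import SUBBAND_NAMES
from oracles import (
    gldm_dependence_enumeration,
    glcm_pair_enumeration,
    glrlm_run_enumeration,
)


def _random_levels(rng, shape=(4, 4, 4), n_levels=3, mask_prob=0.85):
    levels = rng.integers(1, n_levels + 1, size=shape)
    levels[rng.random(shape) > mask_prob] = 0
    if not (levels > 0).any():
        levels[0, 0, 0] = 1
    return levels


class TestPreprocess:
    def test_discretize_consecutive_integers_map_to_all_levels(self):
        levels, _ = discretize(np.arange(32, dtype=float), n_bins=32)
        assert (np.sort(levels) == np.arange(1, 33)).all()

    def test_extremes_occupy_first_and_last_bins(self, rng):
        v = rng.uniform(-5, 20, 200)
        levels, _ = discretize(v, n_bins=16)
        assert levels[np.argmin(v)] == 1
        assert levels[np.argmax(v)] == 16

    def test_not_invariant_to_nonlinear_monotone_transform(self, rng):
        v = rng.uniform(1, 50, 100)
        a, _ = discretize(v, n_bins=8)
        b, _ = discretize(np.log(v), n_bins=8)
        assert not (a == b).all()  # equal-width bins rescale with the transform

    def test_constant_region_warns_level_one(self):
        with pytest.warns(UserWarning, match="constant"):
            levels, _ = discretize(np.full(10, 3.0))
        assert (levels == 1).all()

    def test_resample_2mm_to_1mm_doubles_extent(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(10, 10, 10))
        mask = np.zeros((10, 10, 10), bool)
        mask[4:7, 4:7, 4:7] = True
        out_img, out_mask = resample_isotropic(img, mask, (2.0, 2.0, 2.0))
        assert out_img.shape == (20, 20, 20)
        assert out_mask.dtype == bool and out_mask.any()

    def test_resample_identity_at_target_spacing(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(8, 8, 8))
        mask = np.ones((8, 8, 8), bool)
        out_img, out_mask = resample_isotropic(img, mask, (1.0, 1.0, 1.0))
        assert np.allclose(out_img, img, atol=1e-6)
        assert (out_mask == mask).all()


class TestShape:
    def test_digital_ball_approaches_analytic_sphere(self):
        r = 20
        ax = np.arange(-24, 25)
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        mask = x**2 + y**2 + z**2 <= r**2
        feats = shape_features(mask, (1.0, 1.0, 1.0))
        assert 0.95 <= feats["Sphericity"] <= 1.0
        assert feats["VoxelVolume"] == mask.sum()
        assert feats["Elongation"] == pytest.approx(1.0, abs=0.02)
        assert feats["Flatness"] == pytest.approx(1.0, abs=0.02)
        assert feats["Maximum3DDiameter"] == pytest.approx(2 * r, rel=0.05)

    def test_box_voxel_volume_exact(self):
        mask = np.zeros((10, 12, 14), bool)
        mask[1:5, 2:8, 3:10] = True  # 4 x 6 x 7 box
        feats = shape_features(mask, (1.0, 1.0, 1.0))
        assert feats["VoxelVolume"] == 4 * 6 * 7

    def test_anisotropic_spacing_scales_volume(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        feats = shape_features(mask, (1.0, 2.0, 0.5))
        assert feats["VoxelVolume"] == pytest.approx(64 * 1.0)

    def test_single_voxel_stays_finite(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        feats = shape_features(mask)
        assert all(np.isfinite(v) for v in feats.values())
        assert 0 < feats["Elongation"] <= 1
        assert 0 < feats["Flatness"] <= 1

    def test_intensity_plays_no_role(self):
        # shape features are a function of the mask alone by construction
        mask = np.zeros((6, 6, 6), bool)
        mask[2:5, 1:5, 2:4] = True
        assert shape_features(mask) == shape_features(mask.copy())


class TestFirstorder:
    def test_hand_computed_values(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        levels = np.array([1, 2, 3, 4])
        feats = firstorder_features(x, levels, voxel_volume=2.0)
        assert feats["Mean"] == pytest.approx(2.5)
        assert feats["Variance"] == pytest.approx(1.25)
        assert feats["RootMeanSquared"] == pytest.approx(np.sqrt(7.5))
        assert feats["Energy"] == pytest.approx(30.0)
        assert feats["TotalEnergy"] == pytest.approx(60.0)
        assert feats["Entropy"] == pytest.approx(2.0)  # 4 equiprobable levels
        assert feats["Uniformity"] == pytest.approx(0.25)

    def test_constant_region_degenerates_cleanly(self):
        x = np.full(9, 5.0)
        feats = firstorder_features(x, np.ones(9, dtype=int))
        assert feats["Variance"] == 0.0
        assert feats["Entropy"] == 0.0
        assert feats["Uniformity"] == 1.0
        assert feats["Skewness"] == 0.0

    def test_intensity_scaling_property(self, rng):
        x = rng.uniform(1, 10, 50)
        levels = np.ones(50, dtype=int)
        base = firstorder_features(x, levels)
        scaled = firstorder_features(3.0 * x, levels)
        assert scaled["Mean"] == pytest.approx(3 * base["Mean"])
        assert scaled["RootMeanSquared"] == pytest.approx(3 * base["RootMeanSquared"])
        assert scaled["Variance"] == pytest.approx(9 * base["Variance"])


class TestTextureMatrices:
    @pytest.mark.parametrize("seed", range(4))
    def test_glcm_counts_match_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        levels = _random_levels(rng, shape=(4, 5, 4), n_levels=4)
        for off in direction_offsets_13():
            expected = glcm_pair_enumeration(levels, off, 4)
            assert (glcm_matrix(levels, off, 4) == expected).all()

    @pytest.mark.parametrize("seed", range(4))
    def test_glrlm_counts_match_run_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        levels = _random_levels(rng, shape=(5, 4, 5), n_levels=3)
        for off in direction_offsets_13():
            got = glrlm_matrix(levels, off, 3)
            expected = glrlm_run_enumeration(levels, off, 3, got.shape[1])
            assert (got == expected).all()

    def test_checkerboard_glcm_has_no_diagonal_mass(self):
        levels = np.indices((3, 3, 1)).sum(axis=0) % 2 + 1
        mat = glcm_matrix(levels, (1, 0, 0), 2)
        assert mat[0, 0] == 0 and mat[1, 1] == 0
        feats = _glcm_features_single(mat)
        assert feats["Contrast"] == pytest.approx(1.0)  # |i-j| = 1 everywhere

    def test_level_offset_leaves_difference_features_unchanged(self, rng):
        levels = _random_levels(rng, n_levels=3)
        shifted = np.where(levels > 0, levels + 2, 0)
        base = {}
        moved = {}
        for off in direction_offsets_13():
            m1, m2 = glcm_matrix(levels, off, 3), glcm_matrix(shifted, off, 5)
            if m1.sum() == 0:
                continue
            f1, f2 = _glcm_features_single(m1), _glcm_features_single(m2)
            for key in ("Contrast", "DifferenceAverage", "DifferenceEntropy"):
                assert f2[key] == pytest.approx(f1[key], abs=1e-9), (off, key)

    def test_glszm_counts_on_crafted_zones(self):
        levels = np.zeros((4, 4, 1), dtype=int)
        levels[0, 0:2, 0] = 1  # one zone of size 2
        levels[2:4, 2:4, 0] = 2  # one zone of size 4
        levels[3, 0, 0] = 1  # isolated zone of size 1
        S = glszm_matrix(levels, 2)
        assert S[0, 0] == 1 and S[0, 1] == 1  # level 1: sizes 1 and 2
        assert S[1, 3] == 1  # level 2: size 4

    @pytest.mark.parametrize("seed", range(3))
    def test_gldm_matches_dependence_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        levels = _random_levels(rng, shape=(4, 4, 4), n_levels=3)
        expected = gldm_dependence_enumeration(levels, 3)
        feats = texture_features(levels, "gldm", 3)
        n_z = expected.sum()
        d = np.arange(1, expected.shape[1] + 1)
        assert feats["LargeDependenceEmphasis"] == pytest.approx(
            (expected * d**2).sum() / n_z
        )
        i = np.arange(1, 4)[:, None]
        assert feats["HighGrayLevelEmphasis"] == pytest.approx(
            (expected * i**2).sum() / n_z
        )

    def test_constant_region_has_null_texture(self):
        levels = np.ones((4, 4, 4), dtype=int)
        glcm = texture_features(levels, "glcm", 1)
        assert glcm["Contrast"] == 0.0
        assert glcm["JointEntropy"] == 0.0
        ngtdm = texture_features(levels, "ngtdm", 1)
        assert ngtdm["Contrast"] == 0.0

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown texture family"):
            texture_features(np.ones((3, 3, 3), int), "glxx", 1)

    def test_direction_averaged_features_rotation_invariant(self, rng):
        levels = _random_levels(rng, shape=(5, 5, 5), n_levels=4)
        rotated = np.rot90(levels, k=1, axes=(0, 1))
        for family in ("glcm", "glrlm", "glszm", "ngtdm", "gldm"):
            a = texture_features(levels, family, 4)
            b = texture_features(rotated, family, 4)
            for key in a:
                assert b[key] == pytest.approx(a[key], abs=1e-9), (family, key)


class TestWavelet:
    def test_constant_image_concentrates_in_lll(self):
        img = np.full((6, 6, 6), 4.0)
        bands = haar_subbands(img)
        assert np.allclose(bands["LLL"], 4.0 * 2**1.5)
        for name in SUBBAND_NAMES:
            if name != "LLL":
                assert np.allclose(bands[name], 0.0)

    def test_eight_uniquely_named_subbands(self, rng):
        bands = haar_subbands(rng.normal(size=(4, 4, 4)))
        assert sorted(bands) == sorted(SUBBAND_NAMES)
        assert len(bands) == 8

    def test_matches_pywt_stationary_transform(self, rng):
        """Same filter bank as pywt.swtn, up to its grid shift and the
        detail-filter sign convention."""
        img = rng.normal(size=(8, 8, 8))
        mine = haar_subbands(img)
        ref = pywt.swtn(img, "haar", level=1)[0]
        for name, arr in mine.items():
            key = "".join("a" if c == "L" else "d" for c in name)
            sign = (-1.0) ** name.count("H")
            aligned = sign * np.roll(ref[key], (1, 1, 1), axis=(0, 1, 2))
            assert np.allclose(arr, aligned, atol=1e-10)

    def test_undecimated_frame_preserves_energy(self, rng):
        img = rng.normal(size=(8, 8, 8))
        bands = haar_subbands(img)
        total = sum((b**2).sum() for b in bands.values())
        # tight frame with redundancy 8: subband energy = 8 x input energy
        assert total == pytest.approx(8.0 * (img**2).sum(), rel=1e-9)

    def test_thin_axis_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            haar_subbands(np.ones((1, 4, 4)))


class TestExtraction:
    def test_identical_channels_give_identical_features(self, imaging_cohort):
        sid = imaging_cohort.sample_ids[0]
        vol = imaging_cohort.volumes[sid]["T1"]
        mask = imaging_cohort.masks[sid]
        vec = extract_feature_vector({"A": vol, "B": vol.copy()}, mask)
        a = vec.filter(like="A__").to_numpy()
        b = vec.filter(like="B__").to_numpy()
        assert np.array_equal(a, b)

    def test_repeat_extraction_bit_identical(self, imaging_cohort):
        sid = imaging_cohort.sample_ids[1]
        args = (imaging_cohort.volumes[sid], imaging_cohort.masks[sid])
        v1 = extract_feature_vector(*args)
        v2 = extract_feature_vector(*args)
        assert v1.equals(v2)

    def test_full_inventory_structure(self, imaging_cohort):
        sid = imaging_cohort.sample_ids[0]
        vec = extract_feature_vector(
            imaging_cohort.volumes[sid], imaging_cohort.masks[sid]
        )
        assert len(vec) == 3404
        assert vec.index.is_unique
        t1 = [k for k in vec.index if k.startswith("T1__")]
        assert len(t1) == 851
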