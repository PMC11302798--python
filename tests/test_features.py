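import numpy as np
import pytest

import oracles as orc
from conftest import ball_mask, random_droi, textured_tumor
from radicc.features import (FEATURE_CLASSES, ExtractionConfig, FeatureId,
                             all_feature_ids, discretize, extract_features,
                             firstorder_features, gldm_features,
                             glcm_features, glrlm_features, glszm_features,
                             glszm_matrix, ngtdm_features, shape_features)
from radicc.features.discretize import DiscretizedROI
from radicc.volumes import DegenerateROIError, ImageVolume, LabelMask


def constant_droi(value=5.0, shape=(3, 3, 3), bin_width=25.0):
    lv = np.ones(shape, dtype=np.int32)
    raw = np.full(int(np.prod(shape)), value)
    return DiscretizedROI(levels=lv, raw=raw, ng=1, bin_width=bin_width,
                          bin_origin=value, spacing=(1.0, 1.0, 1.0))


class TestDiscretize:
    def test_formula_on_hand_example(self):
        img = ImageVolume(np.array([10.0, 20.0, 40.0]).reshape(3, 1, 1), (1, 1, 1))
        mask = LabelMask(np.ones((3, 1, 1), np.uint8), (1, 1, 1))
        droi = discretize(img, mask, bin_width=25.0)
        assert droi.levels.ravel().tolist() == [1, 1, 2]
        assert droi.ng == 2
        assert droi.bin_origin == 10.0

    def test_constant_roi_is_single_level(self):
        img = ImageVolume(np.full((4, 4, 4), 3.3), (1, 1, 1))
        mask = LabelMask(np.ones((4, 4, 4), np.uint8), (1, 1, 1))
        droi = discretize(img, mask, 25.0)
        assert droi.ng == 1
        assert set(droi.levels.ravel()) == {1}

    def test_halving_bin_width_never_decreases_levels(self, rng):
        for _ in range(20):
            vals = rng.normal(0, 100, (5, 5, 5))
            img = ImageVolume(vals, (1, 1, 1))
            mask = LabelMask((rng.random((5, 5, 5)) > 0.3).astype(np.uint8),
                             (1, 1, 1))
            if mask.foreground_count == 0:
                continue
            w = float(rng.uniform(5, 50))
            assert (discretize(img, mask, w / 2).ng
                    >= discretize(img, mask, w).ng)

    def test_empty_roi_raises(self):
        img = ImageVolume(np.zeros((3, 3, 3)), (1, 1, 1))
        mask = LabelMask(np.zeros((3, 3, 3), np.uint8), (1, 1, 1))
        with pytest.raises(DegenerateROIError):
            discretize(img, mask, 25.0)


class TestFirstOrder:
    def test_three_value_hand_example(self):
        img = ImageVolume(np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1), (1, 1, 1))
        mask = LabelMask(np.ones((3, 1, 1), np.uint8), (1, 1, 1))
        f = firstorder_features(discretize(img, mask, 1.0))
        assert f["Maximum"] == 3 and f["Median"] == 2
        assert f["Range"] == 2 and f["Mean"] == 2

    def test_constant_roi_degenerate_conventions(self):
        f = firstorder_features(constant_droi(value=7.0))
        assert f["Variance"] == 0 and f["Uniformity"] == 1
        assert f["Entropy"] == 0 and f["Maximum"] == f["Median"] == 7.0
        assert f["Skewness"] == 0 and f["Kurtosis"] == 0

    def test_random_values_match_naive_reference(self, rng):
        vals = rng.normal(50, 20, 200)
        img = ImageVolume(vals.reshape(200, 1, 1), (1.0, 1.5, 2.0))
        mask = LabelMask(np.ones((200, 1, 1), np.uint8), (1.0, 1.5, 2.0))
        droi = discretize(img, mask, 7.0)
        mine = firstorder_features(droi)
        ref = orc.firstorder_features_naive(droi.raw, droi.histogram(),
                                            droi.spacing)
        for name, val in ref.items():
            assert mine[name] == pytest.approx(val, rel=1e-9), name


class TestShape:
    def test_cube_volume_and_surface(self):
        mask = LabelMask(np.pad(np.ones((10, 10, 10), np.uint8), 2), (1, 1, 1))
        f = shape_features(mask)
        assert f["VoxelVolume"] == pytest.approx(1000.0)
        # marching cubes bevels the sharp edges and corners, so mesh area
        # and volume sit a few percent below the analytic 600 mm^2 / 1000 mm^3
        assert f["SurfaceArea"] == pytest.approx(600.0, rel=0.07)
        assert f["MeshVolume"] == pytest.approx(1000.0, rel=0.05)

    def test_sphericity_bounded_and_high_for_balls(self, rng):
        ball = ball_mask((24, 24, 24), 10)
        assert 0.9 < shape_features(ball)["Sphericity"] <= 1.0
        for _ in range(5):
            blob = (rng.random((8, 8, 8)) > 0.4).astype(np.uint8)
            if blob.sum() < 2:
                continue
            f = shape_features(LabelMask(blob, (1, 1, 1)))
            assert f["Sphericity"] <= 1.0

    def test_max_diameter_matches_brute_force(self, rng):
        for _ in range(5):
            blob = (rng.random((12, 12, 12)) > 0.5)
            if not blob.any():
                continue
            mask = LabelMask(blob.astype(np.uint8), (1.0, 1.5, 2.0))
            f = shape_features(mask)
            bnd = np.asarray(orc.boundary_set(blob), dtype=float) * [1.0, 1.5, 2.0]
            expected = max(np.linalg.norm(p - q) for p in bnd for q in bnd)
            assert f["Maximum3DDiameter"] == pytest.approx(expected, rel=1e-9)

    def test_single_voxel_mask_is_finite(self):
        m = np.zeros((3, 3, 3), np.uint8)
        m[1, 1, 1] = 1
        f = shape_features(LabelMask(m, (1, 1, 1)))
        assert all(np.isfinite(v) for v in f.values())


class TestGLCM:
    def test_constant_roi_degenerate_conventions(self):
        f = glcm_features(constant_droi())
        assert f["ClusterShade"] == 0 and f["ClusterProminence"] == 0
        assert f["MaximumProbability"] == 1 and f["MCC"] == 1

    def test_tiny_line_roi_matches_enumeration(self):
        lv = np.array([1, 1, 2, 2], dtype=np.int32).reshape(1, 1, 4)
        droi = DiscretizedROI(levels=lv, raw=lv.ravel().astype(float), ng=2,
                              bin_width=1.0, bin_origin=0.0, spacing=(1, 1, 1))
        mine = glcm_features(droi)
        ref = orc.glcm_features_naive(lv)
        for name, val in ref.items():
            assert mine[name] == pytest.approx(val, rel=1e-9, abs=1e-12), name

    def test_matrices_normalize_and_symmetrize(self, rng):
        from radicc.features import glcm_matrices
        droi = random_droi(rng, (6, 6, 6))
        for mat in glcm_matrices(droi):
            np.testing.assert_allclose(mat, mat.T)
        f = glcm_features(droi)
        assert np.isfinite(list(f.values())).all()

    def test_named_subset_equals_full_computation(self, rng):
        droi = random_droi(rng, (5, 5, 5))
        full = glcm_features(droi)
        subset = glcm_features(droi, names={"MCC", "ClusterShade", "Imc2"})
        assert set(subset) == {"MCC", "ClusterShade", "Imc2"}
        for name, val in subset.items():
            assert val == full[name]


class TestRunZoneDependence:
    def test_constant_cube_has_one_zone_and_zero_variance(self):
        droi = constant_droi(shape=(3, 3, 3))
        szm = glszm_matrix(droi)
        assert szm.shape == (1, 27) and szm[0, 26] == 1
        assert glszm_features(droi)["GrayLevelVariance"] == 0
        assert ngtdm_features(droi)["Complexity"] == 0

    def test_tiny_line_roi_matches_enumeration(self):
        lv = np.array([1, 1, 1, 2, 2], dtype=np.int32).reshape(1, 1, 5)
        droi = DiscretizedROI(levels=lv, raw=lv.ravel().astype(float), ng=2,
                              bin_width=1.0, bin_origin=0.0, spacing=(1, 1, 1))
        for mine, ref in [(glrlm_features(droi), orc.glrlm_features_naive(lv)),
                          (glszm_features(droi), orc.glszm_features_naive(lv)),
                          (gldm_features(droi), orc.gldm_features_naive(lv)),
                          (ngtdm_features(droi), orc.ngtdm_features_naive(lv))]:
            for name, val in ref.items():
                assert mine[name] == pytest.approx(val, rel=1e-9, abs=1e-12), name

    def test_zone_sizes_partition_the_roi(self, rng):
        for _ in range(10):
            droi = random_droi(rng, (5, 5, 5))
            szm = glszm_matrix(droi)
            sizes = np.arange(1, szm.shape[1] + 1)
            assert (szm * sizes).sum() == droi.n_voxels

    def test_single_voxel_roi_is_defined(self):
        lv = np.ones((1, 1, 1), dtype=np.int32)
        droi = DiscretizedROI(levels=lv, raw=np.array([4.0]), ng=1,
                              bin_width=1.0, bin_origin=4.0, spacing=(1, 1, 1))
        for fn in (glrlm_features, glszm_features, gldm_features,
                   ngtdm_features, glcm_features):
            vals = fn(droi)
            assert all(np.isfinite(v) for v in vals.values()), fn.__name__


class TestPanel:
    def test_default_panel_has_944_features(self):
        ids = all_feature_ids()
        assert len(ids) == 944
        shape_ids = [f for f in ids if f.feature_class == "shape"]
        assert len(shape_ids) == 14
        assert all(f.image_type == "original" for f in shape_ids)
        per_type = {}
        for f in ids:
            if f.feature_class != "shape":
                per_type.setdefault(f.image_type, []).append(f)
        assert len(per_type) == 10
        assert all(len(v) == 93 for v in per_type.values())

    def test_extraction_is_deterministic_and_finite(self, rng):
        img, mask = textured_tumor(rng)
        s1 = extract_features(img, mask)
        s2 = extract_features(img, mask)
        assert len(s1) == 944
        assert np.isfinite(s1.to_numpy()).all()
        assert (s1.to_numpy() == s2.to_numpy()).all()

    def test_intensity_shift_equivariance(self, rng):
        img, mask = textured_tumor(rng)
        base = extract_features(img, mask)
        shifted = extract_features(img.with_voxels(img.voxels + 1000.0), mask)
        sh_b = base.loc[("original", "shape")]
        sh_s = shifted.loc[("original", "shape")]
        np.testing.assert_allclose(sh_s.to_numpy(), sh_b.to_numpy(), rtol=1e-12)
        fo_b = base.loc[("original", "firstorder")]
        fo_s = shifted.loc[("original", "firstorder")]
        assert fo_s["Maximum"] == pytest.approx(fo_b["Maximum"] + 1000.0)
        assert fo_s["Median"] == pytest.approx(fo_b["Median"] + 1000.0)
        # texture is invariant: bin origin tracks the ROI minimum
        tex_b = base.loc[("original", "glcm")]
        tex_s = shifted.loc[("original", "glcm")]
        np.testing.assert_allclose(tex_s.to_numpy(), tex_b.to_numpy(), rtol=1e-9)

    def test_subset_extraction_matches_full(self, rng):
        img, mask = textured_tumor(rng)
        full = extract_features(img, mask)
        want = [FeatureId("original", "shape", "Sphericity"),
                FeatureId("wavelet-LLL", "glcm", "MCC"),
                FeatureId("log-sigma-1-0-mm-3D", "ngtdm", "Complexity")]
        sub = extract_features(img, mask, subset=want)
        assert len(sub) == 3
        for fid in want:
            assert sub[tuple(fid)] == full[tuple(fid)]

    def test_class_name_counts_sum_to_93(self):
        counts = {c: len(n) for c, n in FEATURE_CLASSES.items()}
        assert counts == {"firstorder": 18, "glcm": 24, "glrlm": 16,
                          "glszm": 16, "gldm": 14, "ngtdm": 5}
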