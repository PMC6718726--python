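"""Feature catalogue: ROI machinery, shape/intensity/texture operators, full vector."""

import numpy as np
import pytest

import radiosurv as rs
from radiosurv.features import (FEATURE_NAMES, N_FEATURES, N_PER_BLOCK,
                                DegenerateTextureError,
                                EmptyRegionError, GlcmSpec, OFFSET_0DEG,
                                OFFSET_45DEG, RoiPatch, _haralick, crop_roi,
                                glcm_matrix, hog_descriptor, lbp_histogram,
                                quantize, select_slice)
from radiosurv.io_preprocess import TumorMasks


def _patch(img, mask=None):
    img = np.asarray(img, dtype=np.float64)
    mask = np.ones_like(img, dtype=bool) if mask is None else np.asarray(mask, bool)
    return RoiPatch(image2d=img, mask2d=mask)


class TestSliceSelection:
    def test_single_voxel_selects_its_axial_index(self):
        m = np.zeros((5, 5, 7), dtype=bool)
        m[2, 3, 4] = True
        assert select_slice(m) == ("axial", 4)

    def test_ellipsoid_selects_equatorial_slice(self):
        z, y, x = np.ogrid[0:21, 0:21, 0:15]
        m = ((z - 10) / 8) ** 2 + ((y - 10) / 6) ** 2 + ((x - 7) / 5) ** 2 <= 1
        assert select_slice(m) == ("axial", 7)

    def test_tie_breaks_to_lowest_index(self):
        m = np.zeros((4, 4, 5), dtype=bool)
        m[0, 0, 1] = m[0, 0, 3] = True
        assert select_slice(m)[1] == 1

    def test_empty_mask_signals(self):
        with pytest.raises(EmptyRegionError):
            select_slice(np.zeros((3, 3, 3), dtype=bool))


class TestCropRoi:
    def test_full_frame_mask_is_identity(self):
        img = np.arange(12.0).reshape(3, 4)
        p = crop_roi(img, np.ones((3, 4), dtype=bool))
        np.testing.assert_array_equal(p.image2d, img)
        assert p.bounding_box == (0, 0, 3, 4)

    def test_single_pixel_mask(self):
        img = np.arange(9.0).reshape(3, 3)
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 2] = True
        p = crop_roi(img, mask)
        assert p.image2d.shape == (1, 1) and p.image2d[0, 0] == 5.0

    def test_l_shaped_mask_keeps_shape_inside_tight_box(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[1:5, 1] = True
        mask[4, 1:4] = True
        p = crop_roi(np.zeros((6, 6)), mask)
        assert p.bounding_box == (1, 1, 5, 4)
        assert p.mask2d.sum() == mask.sum()
        assert not p.mask2d[0, 2]  # the L's notch stays outside the mask


class TestShapeFeatures:
    def test_single_voxel_volume(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        brain = np.ones_like(m)
        out = rs.shape_features(m, brain, 2, (1.0, 1.0, 1.0))
        assert out["TumorVolume"] == 1.0
        assert out["BrainVolume"] == 125.0

    def test_disc_is_round_and_solid(self):
        y, x = np.ogrid[0:31, 0:31]
        disc2d = (y - 15) ** 2 + (x - 15) ** 2 <= 10 ** 2
        m = np.zeros((31, 31, 3), dtype=bool)
        m[:, :, 1] = disc2d
        out = rs.shape_features(m, np.ones_like(m), 1, (1.0, 1.0, 1.0))
        assert out["Eccentricity"] < 0.1
        assert out["Solidity"] > 0.9  # digitized circle; hull of pixel centers

    def test_rectangle_closed_forms(self):
        m = np.zeros((20, 30, 3), dtype=bool)
        m[5:15, 5:25, 1] = True  # 10 x 20 filled rectangle
        out = rs.shape_features(m, np.ones_like(m), 1, (1.0, 1.0, 1.0))
        assert out["Extent"] == 1.0
        assert out["TumorArea"] == 200.0
        assert out["EquivalentDiameter"] == pytest.approx(np.sqrt(4 * 200 / np.pi))

    def test_voxel_volume_scales_with_spacing(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[1, 1, 1] = True
        out = rs.shape_features(m, np.ones_like(m), 1, (2.0, 2.0, 2.0))
        assert out["TumorVolume"] == 8.0


class TestJointShapeFeatures:
    @staticmethod
    def _masks(n_at, n_tc, n_wt):
        wt = np.zeros((4, 4, 4), dtype=bool)
        flat = wt.reshape(-1)
        flat[:n_wt] = True
        tc = np.zeros_like(wt)
        tc.reshape(-1)[:n_tc] = True
        at = np.zeros_like(wt)
        at.reshape(-1)[:n_at] = True
        return TumorMasks(wt=wt, tc=tc, at=at, brain=np.ones_like(wt))

    def test_identical_masks_give_unit_ratios(self):
        m = self._masks(4, 4, 4)
        assert rs.joint_shape_features(m) == {
            "ATtoWTVolumeRatio": 1.0, "TCtoWTVolumeRatio": 1.0, "ATtoTCVolumeRatio": 1.0}

    def test_counted_ratios(self):
        out = rs.joint_shape_features(self._masks(1, 2, 4))
        assert (out["ATtoWTVolumeRatio"], out["TCtoWTVolumeRatio"],
                out["ATtoTCVolumeRatio"]) == (0.25, 0.5, 0.5)

    def test_empty_at_uses_policy_value(self):
        out = rs.joint_shape_features(self._masks(0, 2, 4))
        assert out["ATtoWTVolumeRatio"] == 0.0
        assert out["TCtoWTVolumeRatio"] == 0.5


class TestIntensityFeatures:
    def test_constant_values(self):
        out = rs.intensity_features(np.array([5, 5, 5, 5]))
        assert out["MinimumIntensity"] == out["MaximumIntensity"] == 5
        assert out["Range"] == 0 and out["Variance"] == 0 and out["Entropy"] == 0

    def test_hand_arithmetic(self):
        out = rs.intensity_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert out["MeanIntensity"] == 2.5
        assert out["Range"] == 3.0
        assert out["RMS"] == pytest.approx(np.sqrt(7.5))
        assert out["Moment2nd"] == pytest.approx(1.25)   # population
        assert out["Variance"] == pytest.approx(5.0 / 3)  # n-1 denominator
        assert out["MeanAbsoluteDeviation"] == 1.0

    def test_two_level_histogram_is_one_bit(self):
        vals = np.array([0] * 50 + [255] * 50)
        assert rs.intensity_features(vals)["Entropy"] == pytest.approx(1.0)


class TestGlcm:
    def test_constant_patch_single_diagonal_cell(self):
        P = glcm_matrix(_patch(np.full((4, 4), 100.0)))
        assert P.sum() == pytest.approx(1.0)
        level = quantize(np.array([[100.0]]), 8)[0, 0]
        assert P[level, level] == pytest.approx(1.0)

    def test_two_level_checkerboard_off_diagonal_mass(self):
        img = np.array([[0.0, 255.0], [255.0, 0.0]])
        P = glcm_matrix(_patch(img), GlcmSpec(offsets=(OFFSET_0DEG,)))
        assert P[0, 7] == pytest.approx(0.5) and P[7, 0] == pytest.approx(0.5)
        assert P[0, 0] == 0 and P[7, 7] == 0

    def test_checkerboard_contrast_is_squared_level_distance(self):
        img = np.tile(np.array([[0.0, 255.0], [255.0, 0.0]]), (4, 4))
        out = rs.glcm_features(_patch(img))
        assert out["Contrast"] == pytest.approx(49.0)  # levels 0 and 7
        assert out["Energy"] == pytest.approx(0.5)

    def test_constant_patch_statistics(self):
        out = rs.glcm_features(_patch(np.full((6, 6), 42.0)))
        assert out["Contrast"] == 0.0
        assert out["Energy"] == 1.0
        assert out["Homogeneity"] == 1.0
        assert out["Entropy"] == 0.0

    def test_single_masked_pixel_is_degenerate(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = True
        with pytest.raises(DegenerateTextureError):
            glcm_matrix(_patch(np.random.default_rng(0).random((4, 4)) * 255, mask))

    def test_matrix_sums_to_one(self, random_patches):
        for img, mask in random_patches[:20]:
            P = glcm_matrix(_patch(img, mask),
                            GlcmSpec(offsets=(OFFSET_0DEG, OFFSET_45DEG)))
            assert abs(P.sum() - 1.0) < 1e-12

    def test_accumulated_offsets_are_more_rotation_stable(self):
        # stripes whose 45-degree rotation is exact on the grid: the
        # accumulated-offset statistics barely move, single-offset ones jump
        ii, jj = np.mgrid[0:32, 0:32]
        horiz = (255 * ((ii // 4) % 2)).astype(float)
        diag = (255 * (((ii + jj) // 4) % 2)).astype(float)
        single, accum = [], []
        for name in ("SumEntropy", "DifferenceEntropy", "SumVariance2_",
                     "DifferenceVariance"):
            s = [_haralick(glcm_matrix(_patch(img), GlcmSpec(offsets=(OFFSET_0DEG,))))[name]
                 for img in (horiz, diag)]
            a = [_haralick(glcm_matrix(_patch(img),
                                       GlcmSpec(offsets=(OFFSET_0DEG, OFFSET_45DEG))))[name]
                 for img in (horiz, diag)]
            single.append(abs(s[0] - s[1]))
            accum.append(abs(a[0] - a[1]))
        assert np.mean(accum) < np.mean(single)


class TestHog:
    def test_constant_patch_all_zero(self):
        out = rs.hog_features(_patch(np.full((16, 16), 77.0)))
        assert out == {"SumHOG": 0.0, "MedianHOG": 0.0, "StdHOG": 0.0}

    def test_vertical_step_edge_concentrates_one_orientation(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 255.0
        d = hog_descriptor(_patch(img))
        assert d.sum() > 0
        bins = d.reshape(-1, 9).sum(axis=0)
        assert bins.max() / bins.sum() > 0.5  # one dominant orientation bin

    def test_summaries_consistent_with_descriptor(self, random_patches):
        img, mask = random_patches[0]
        d = hog_descriptor(_patch(img, mask))
        out = rs.hog_features(_patch(img, mask))
        assert out["SumHOG"] == pytest.approx(d.sum())
        assert out["MedianHOG"] == pytest.approx(np.median(d))
        assert out["StdHOG"] == pytest.approx(d.std())

    def test_small_patch_padded(self):
        out = rs.hog_features(_patch(np.array([[1.0, 200.0], [90.0, 3.0]])))
        assert np.isfinite(list(out.values())).all()


class TestLbp:
    def test_constant_patch_single_bin(self):
        h = lbp_histogram(_patch(np.full((6, 6), 50.0)))
        assert h.max() == pytest.approx(1.0)
        assert (h > 0).sum() == 1

    def test_histogram_normalized(self, random_patches):
        for img, mask in random_patches[:10]:
            assert lbp_histogram(_patch(img, mask)).sum() == pytest.approx(1.0)

    def test_features_from_histogram(self):
        img = np.random.default_rng(5).integers(0, 256, (8, 8)).astype(float)
        h = lbp_histogram(_patch(img))
        out = rs.lbp_features(_patch(img))
        assert out["SumLBP"] == pytest.approx(h.sum())
        assert out["MeanLBP"] == pytest.approx(h.mean())
        assert out["StdLBP"] == pytest.approx(h.std())


class TestFullVector:
    def test_catalogue_counts_and_names(self):
        assert N_FEATURES == 147
        assert N_PER_BLOCK == 48
        assert len(FEATURE_NAMES) == 147
        assert len(set(FEATURE_NAMES)) == 147
        assert FEATURE_NAMES[138] == "T2_TC_SumHOG_F139"
        assert FEATURE_NAMES[0].startswith("T2-FLAIR_WT_")
        assert FEATURE_NAMES[-1] == "mpMRI_Joint_ATtoTCVolumeRatio_F147"

    def test_extract_all_returns_147_finite(self, normalized_study):
        study, masks = normalized_study
        fv = rs.extract_all(study, masks)
        assert len(fv) == 147
        assert np.isfinite(fv.to_numpy()).all()

    def test_extract_all_deterministic(self, normalized_study):
        study, masks = normalized_study
        a = rs.extract_all(study, masks)
        b = rs.extract_all(study, masks)
        assert (a == b).all()

    def test_empty_at_block_gets_policy_values(self):
        study = rs.generate_phantom_study(rs.PhantomConfig(seed=4))
        labels = study.labels.copy()
        labels[labels == 4] = 1  # erase the enhancing tumor
        study = rs.MriStudy(patient_id="noAT", channels=study.channels,
                            labels=labels, voxel_mm=study.voxel_mm)
        masks = rs.study_masks(study)
        norm = rs.normalize_study(study, masks)
        qc = []
        fv = rs.extract_all(norm, masks, qc=qc)
        assert len(fv) == 147
        at_block = [n for n in FEATURE_NAMES if n.startswith("T1-Gd_AT_")]
        assert len(at_block) == 48
        assert (fv[at_block] == 0.0).all()
        assert any("T1-Gd_AT" in line for line in qc)
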