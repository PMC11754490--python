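"""Aorta shape classification, reference slice, corridor, sector split."""

import numpy as np
import pytest
from skimage.draw import disk, ellipse

from chestcac import phantom as ph
from chestcac import region_split as rs
from chestcac.ct_io import BinaryMask


def _as_mask(bits2d_stack, spacing=(0.7, 0.7, 2.5)):
    return BinaryMask(bits2d_stack, spacing)


class TestShapeClassification:
    def test_disk_is_circular(self):
        m = np.zeros((64, 64), bool)
        m[disk((32, 32), 10)] = True
        assert rs.classify_aorta_shape(m).shape is rs.AortaShape.CIRCULAR

    def test_2_to_1_ellipse_is_elliptical(self):
        m = np.zeros((64, 64), bool)
        m[ellipse(32, 32, 20, 10)] = True
        s = rs.classify_aorta_shape(m)
        assert s.shape is rs.AortaShape.ELLIPTICAL
        assert s.axis_ratio >= 1.25

    def test_notched_ellipse_is_semi_elliptical(self):
        m = np.zeros((64, 64), bool)
        m[ellipse(32, 32, 12, 20)] = True
        bite = np.zeros_like(m)
        bite[disk((32, 44), 12)] = True
        s = rs.classify_aorta_shape(m & ~bite)
        assert s.shape is rs.AortaShape.SEMI_ELLIPTICAL
        assert s.solidity < 0.9

    def test_empty_mask_is_absent(self):
        s = rs.classify_aorta_shape(np.zeros((32, 32), bool))
        assert s.shape is rs.AortaShape.ABSENT


class TestReferenceSlice:
    def test_first_elliptical_slice_found_from_phantom_schedule(self, default_phantom):
        _, _, truth = default_phantom
        profile = rs.build_aorta_profile(truth.aorta)
        assert rs.find_reference_slice(profile) == truth.reference_slice

    def test_phantom_profile_follows_schedule(self, default_phantom):
        spec, _, truth = default_phantom
        classes = rs.build_aorta_profile(truth.aorta).classes()
        assert classes[0] is rs.AortaShape.CIRCULAR
        assert classes[spec.first_elliptical_slice] is rs.AortaShape.ELLIPTICAL
        assert classes[spec.first_semi_elliptical_slice] is rs.AortaShape.SEMI_ELLIPTICAL
        assert classes[spec.aorta_last_slice + 1] is rs.AortaShape.ABSENT

    def test_all_circular_profile_raises_with_fallback_hint(self):
        bits = np.zeros((64, 64, 6), bool)
        bits[disk((32, 32), 8)[0], disk((32, 32), 8)[1], :] = True
        profile = rs.build_aorta_profile(_as_mask(bits))
        with pytest.raises(rs.ReferenceSliceNotFound, match="fallback"):
            rs.find_reference_slice(profile)

    def test_fallback_picks_maximum_area_slice(self):
        bits = np.zeros((64, 64, 4), bool)
        bits[disk((32, 32), 5)[0], disk((32, 32), 5)[1], 1] = True
        bits[disk((32, 32), 9)[0], disk((32, 32), 9)[1], 2] = True
        assert rs.fallback_reference_slice(_as_mask(bits)) == 2

    def test_localization_offset_arithmetic(self):
        assert rs.localization_slice(0, 10.0, 2.5) == 4  # ceil(10/2.5)
        assert rs.localization_slice(12, 10.0, 2.5) == 16
        assert rs.localization_slice(3, 10.0, 3.0) == 7  # ceil rounds up


class TestCorridor:
    def test_empty_fat_gives_empty_corridor(self):
        fat = _as_mask(np.zeros((32, 32, 4), bool))
        assert rs.coronary_corridor(fat).voxel_count == 0

    def test_corridor_contains_fat_on_random_phantoms(self, batch20):
        assert all(rec.corridor_contains_fat for rec in batch20)

    def test_corridor_covers_truth_lesions(self, default_phantom, default_result):
        _, _, truth = default_phantom
        corridor = rs.coronary_corridor(default_result.organ_masks.epicardial_fat)
        for lt in truth.lesions:
            inside = corridor.bits[lt.indices].mean()
            assert inside >= 0.95, lt.artery

    def test_erode_larger_than_dilate_rejected(self):
        fat = _as_mask(np.zeros((8, 8, 2), bool))
        with pytest.raises(ValueError, match="must not exceed"):
            rs.coronary_corridor(fat, dilate_radius_mm=2.0, erode_radius_mm=4.0)


class TestSectorSplit:
    def test_labels_partition_corridor_heart_below_localization(self, default_phantom,
                                                                default_result):
        res = default_result
        labels = res.region_map.labels
        heart = res.organ_masks.heart.bits
        corridor = rs.coronary_corridor(res.organ_masks.epicardial_fat).bits
        loc = res.region_map.localization_slice
        sel = heart & corridor
        sel[:, :, :loc] = False
        sel &= ~res.organ_masks.aorta.bits
        assert (labels[sel] > 0).all()          # full coverage
        assert (labels[~sel & ~res.organ_masks.aorta.bits] == 0).all()  # exclusivity

    def test_aorta_never_labeled_coronary(self, batch20):
        assert all(rec.aorta_never_coronary for rec in batch20)

    def test_canonical_lesions_attributed_to_their_arteries(self, default_phantom,
                                                            default_result):
        _, _, truth = default_phantom
        for lt in truth.lesions:
            lab = default_result.region_map.labels[lt.indices]
            frac = (lab == rs.NAME_LABELS[lt.artery]).mean()
            assert frac >= 0.95, lt.artery

    def test_translation_equivariance_of_region_labels(self):
        # shifting the phantom 5 voxels laterally shifts the labels identically
        spec = ph.PhantomSpec.default()
        shift_vox = 5
        moved = spec.translated(shift_vox * spec.spacing[0], 0.0)

        def labels_from_truth(s):
            _, truth = ph.generate_phantom(s)
            corridor = rs.coronary_corridor(truth.fat)
            return rs.split_heart_regions(truth.heart, truth.aorta, corridor,
                                          truth.reference_slice).labels

        a = labels_from_truth(spec)
        b = labels_from_truth(moved)
        np.testing.assert_array_equal(b[shift_vox:], a[:-shift_vox])

    def test_empty_heart_rejected(self):
        empty = _as_mask(np.zeros((16, 16, 4), bool))
        aorta = _as_mask(np.zeros((16, 16, 4), bool))
        aorta.bits[4:8, 4:8, 0] = True
        with pytest.raises(ValueError, match="heart mask is empty"):
            rs.split_heart_regions(empty, aorta, empty, reference_slice=0)

    def test_sector_params_must_tile(self):
        with pytest.raises(ValueError, match="contiguous"):
            rs.SectorParams(rca=(-100.0, 70.0), lad=(80.0, 200.0))

    def test_sector_label_wraps_angles(self):
        p = rs.SectorParams()
        assert rs.sector_label(np.array([0.0]), p)[0] == rs.RCA
        assert rs.sector_label(np.array([140.0]), p)[0] == rs.LAD
        assert rs.sector_label(np.array([230.0]), p)[0] == rs.LCX
        assert rs.sector_label(np.array([-130.0]), p)[0] == rs.LCX  # wraps to 230
        assert rs.sector_label(np.array([430.0]), p)[0] == rs.RCA   # wraps to 70
        assert rs.sector_label(np.array([80.0]), p)[0] == rs.LAD    # half-open bound
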