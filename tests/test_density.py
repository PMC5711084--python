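"""Threshold segmentation, calibration, bulk schemes, and cropping rules."""

import numpy as np
import pytest

import mribulk as mb
from mribulk import TissueClass
from mribulk.density import build_ct_density, extract_sptv


def _flat_volume(values_1d):
    arr = np.asarray(values_1d, dtype=np.float32).reshape(-1, 1, 1)
    return mb.Volume(arr, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))


class TestSegmentByThreshold:
    @pytest.mark.parametrize(
        "hu,is_bone,is_air",
        [(251.0, True, False), (250.0, False, False), (-300.0, False, False),
         (-301.0, False, True), (0.0, False, False)],
    )
    def test_strict_threshold_boundaries(self, hu, is_bone, is_air):
        ct = _flat_volume([hu])
        bone, air = mb.segment_by_threshold(ct)
        assert bool(bone[0, 0, 0]) is is_bone
        assert bool(air[0, 0, 0]) is is_air

    def test_all_water_body_gives_empty_masks(self):
        ct = _flat_volume(np.zeros(20))
        bone, air = mb.segment_by_threshold(ct)
        assert not bone.any() and not air.any()

    def test_masks_disjoint_and_restricted_to_body(self):
        ct = _flat_volume([500.0, -500.0, 500.0])
        body = np.array([True, True, False]).reshape(-1, 1, 1)
        bone, air = mb.segment_by_threshold(ct, body=body)
        assert not (bone & air).any()
        assert not bone[2].any()

    def test_swapped_thresholds_rejected(self):
        with pytest.raises(ValueError):
            mb.segment_by_threshold(_flat_volume([0.0]), bone_hu=-300, air_hu=250)


class TestCalibrationCurve:
    @pytest.mark.parametrize(
        "hu,red", [(0.0, 1.0), (-1000.0, 0.0), (700.0, 1.45), (1400.0, 1.84), (3071.0, 3.0)]
    )
    def test_anchor_points(self, hu, red):
        curve = mb.CalibrationCurve()
        assert curve(np.array([hu]))[0] == pytest.approx(red, abs=1e-12)

    def test_clamped_outside_domain(self):
        curve = mb.CalibrationCurve()
        assert curve(np.array([-2000.0]))[0] == 0.0
        assert curve(np.array([9000.0]))[0] == 3.0

    def test_linear_between_anchors(self):
        curve = mb.CalibrationCurve()
        assert curve(np.array([350.0]))[0] == pytest.approx(1.0 + 0.45 / 2)

    def test_decreasing_hu_rejected(self):
        with pytest.raises(ValueError):
            mb.CalibrationCurve(hu=np.array([-1000.0, 500.0, 400.0, 3071.0]),
                                red=np.array([0.0, 1.0, 1.2, 3.0]))

    def test_hu_to_red_on_phantom_bone(self, head_phantom):
        labels, ct, _, _ = head_phantom
        red = mb.hu_to_red(ct)
        assert np.allclose(red.values[labels.mask(TissueClass.BONE)], 1.45)


class TestBulkSchemes:
    def test_scheme_w_is_binary_water(self, head_phantom):
        labels, _, _, structs = head_phantom
        red = mb.build_density_scheme(labels, structs["BODY"], "W")
        assert set(np.unique(red.values)) == {0.0, 1.0}
        assert np.all(red.values[structs["BODY"]] == 1.0)

    def test_scheme_wb_bone_assigned_air_watered(self, head_phantom):
        labels, _, _, structs = head_phantom
        red = mb.build_density_scheme(labels, structs["BODY"], "W+B")
        assert np.allclose(red.values[labels.mask(TissueClass.BONE)], 1.45)
        assert np.allclose(red.values[labels.mask(TissueClass.TOOTH)], 1.45)
        assert np.allclose(red.values[labels.mask(TissueClass.AIR)], 1.0)

    def test_scheme_wba_air_zeroed(self, head_phantom):
        labels, _, _, structs = head_phantom
        red = mb.build_density_scheme(labels, structs["BODY"], "W+B+A")
        assert np.allclose(red.values[labels.mask(TissueClass.AIR)], 0.0)
        assert np.allclose(red.values[labels.mask(TissueClass.BONE)], 1.45)

    def test_implants_pass_as_teeth_on_mri_arm(self, implant_phantom):
        labels, _, _, structs = implant_phantom
        red = mb.build_density_scheme(labels, structs["BODY"], "W+B+A")
        assert np.allclose(red.values[labels.mask(TissueClass.IMPLANT)], 1.45)

    def test_ct_arm_overrides(self, implant_phantom):
        labels, ct, _, structs = implant_phantom
        red = build_ct_density(
            ct, structs["BODY"],
            implant_mask=labels.mask(TissueClass.IMPLANT),
            artifact_mask=labels.mask(TissueClass.ARTIFACT),
        )
        assert np.allclose(red.values[labels.mask(TissueClass.IMPLANT)], 3.0)
        assert np.allclose(red.values[labels.mask(TissueClass.ARTIFACT)], 1.0)

    def test_heterogeneity_strictly_increases_across_schemes(self, head_phantom):
        labels, _, _, structs = head_phantom
        body = structs["BODY"]
        het = []
        for s in ("W", "W+B", "W+B+A"):
            red = mb.build_density_scheme(labels, body, s)
            het.append(np.abs(red.values[body] - 1.0).mean())
        assert het[0] == 0.0
        assert het[0] < het[1] < het[2]

    def test_wba_vs_ct_disagrees_only_where_bulk_misses_hu(self, head_phantom):
        """On an implant-free phantom the segment->assign->compare loop
        differs from the CT arm only where the voxel's HU->RED value is off
        its bulk value (soft tissue at HU != 0, tooth enamel above the bulk
        bone density) — never in label class: bone and air agree exactly."""
        labels, ct, _, structs = head_phantom
        body = structs["BODY"]
        scheme = mb.build_density_scheme(labels, body, "W+B+A")
        ct_red = build_ct_density(ct, body)
        differ = ~np.isclose(scheme.values, ct_red.values)
        assert set(np.unique(labels.volume.values[differ])) <= {
            int(TissueClass.SOFT), int(TissueClass.TOOTH)
        }
        bone = labels.mask(TissueClass.BONE)
        air = labels.mask(TissueClass.AIR)
        np.testing.assert_allclose(scheme.values[bone], ct_red.values[bone])
        np.testing.assert_allclose(scheme.values[air], ct_red.values[air])

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            mb.BulkScheme("W+A")

    def test_overlapping_implant_air_rejected(self, head_phantom):
        labels, _, _, structs = head_phantom
        air = labels.mask(TissueClass.AIR)
        with pytest.raises(ValueError):
            mb.build_density_scheme(labels, structs["BODY"], "W+B+A", implant_mask=air)


class TestCropStructures:
    def test_zero_margin_no_cut_is_identity(self, head_phantom):
        *_, structs = head_phantom
        out = mb.crop_structures(structs, inner_margin_mm=0.0)
        for name in structs.names:
            assert np.array_equal(out[name], structs[name])

    def test_metric_margin_boundary(self):
        # slab body at 0.7 mm pitch: voxel depths step by 0.7 mm, so the
        # 5 mm margin falls between voxels at depths 4.9 mm (removed) and
        # 5.6 mm (kept)
        body = np.zeros((31, 31, 5), dtype=bool)
        body[5:26, 5:26, :] = True
        structs = mb.StructureSet(
            {"BODY": body, "PTV70": body.copy()}, (0.7, 0.7, 0.7), (0.0, 0.0, 0.0)
        )
        out = mb.crop_structures(structs, inner_margin_mm=5.0)
        kept = out["PTV70"][:, 15, 2]
        i = np.arange(31)
        depth = 0.7 * np.minimum(i - 4, 26 - i)  # mm to nearest outside voxel
        expect = body[:, 15, 2] & (depth >= 5.0)
        assert kept[11] == False and depth[11] == pytest.approx(4.9)  # noqa: E712
        assert kept[12] == True and depth[12] == pytest.approx(5.6)  # noqa: E712
        assert np.array_equal(kept, expect)

    def test_inferior_cut_and_internal_retention(self, head_phantom):
        *_, structs = head_phantom
        cut = -60.0
        out = mb.crop_structures(structs, inferior_cut_mm=cut)
        zs = structs.origin_mm[2] + structs.spacing_mm[2] * np.arange(
            structs["BODY"].shape[2]
        )
        body_z = zs[np.nonzero(out["BODY"].any(axis=(0, 1)))[0]]
        assert body_z.min() >= cut
        for name in out.names:
            if name == "BODY" or not out[name].any():
                continue
            lo = zs[np.nonzero(out[name].any(axis=(0, 1)))[0]].min()
            assert lo >= cut + 10.0

    def test_idempotent(self, head_phantom):
        *_, structs = head_phantom
        once = mb.crop_structures(structs, inferior_cut_mm=-60.0)
        twice = mb.crop_structures(once, inferior_cut_mm=-60.0)
        for name in once.names:
            assert np.array_equal(once[name], twice[name])

    def test_erosion_emptying_body_rejected(self):
        body = np.ones((4, 4, 4), dtype=bool)
        structs = mb.StructureSet({"BODY": body}, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            mb.crop_structures(structs, inner_margin_mm=50.0)


class TestExtractSptv:
    def test_slice_range_definition(self):
        ptv = np.zeros((4, 4, 25), dtype=bool)
        ptv[:, :, 5:21] = True
        imp = np.zeros_like(ptv)
        imp[1, 1, 10:13] = True
        out = extract_sptv(ptv, imp)
        expect = np.zeros_like(ptv)
        expect[:, :, 10:13] = True
        assert np.array_equal(out, expect)

    def test_implant_spanning_all_slices_returns_struct(self):
        ptv = np.zeros((3, 3, 10), dtype=bool)
        ptv[:, :, 2:8] = True
        imp = np.zeros_like(ptv)
        imp[0, 0, 0] = imp[0, 0, 9] = True
        assert np.array_equal(extract_sptv(ptv, imp), ptv)

    def test_against_per_slice_loop(self, implant_phantom):
        labels, _, _, structs = implant_phantom
        imp = labels.mask(TissueClass.IMPLANT)
        out = extract_sptv(structs["PTV70"], imp)
        # brute-force slice filter
        z_has = [k for k in range(imp.shape[2]) if imp[:, :, k].any()]
        z0, z1 = min(z_has), max(z_has)
        manual = np.zeros_like(out)
        for k in range(z0, z1 + 1):
            manual[:, :, k] = structs["PTV70"][:, :, k]
        assert np.array_equal(out, manual)
        assert out.any()

    def test_empty_implant_rejected(self):
        ptv = np.ones((3, 3, 3), dtype=bool)
        with pytest.raises(ValueError):
            extract_sptv(ptv, np.zeros_like(ptv))
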