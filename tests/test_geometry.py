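"""Unit tests for thickness mapping, projection, ROIs and region metrics."""

import numpy as np
import pytest

from helpers import slab_volume
from conftest import metric_value
from kneequant.geometry import (
    AlignmentError,
    ROIError,
    align_volume,
    compute_thickness_volume,
    define_femoral_rois,
    define_tibial_rois,
    dice_coefficient,
    mean_region_thickness,
    project_thickness,
    projected_area_ratio,
)
from kneequant.render import render_thickness_map
from kneequant.volume import (
    FEMORAL_CARTILAGE,
    FEMUR_BONE,
    LabelVolume,
)


def _make_pmap(thickness2d, footprint=None):
    """Assemble a ProjectedThicknessMap directly for metric unit tests."""
    from kneequant.geometry import ProjectedThicknessMap
    from kneequant.volume import AlignmentRecord

    t = np.asarray(thickness2d, float)
    fp = np.ones_like(t, bool) if footprint is None else footprint
    rec = AlignmentRecord("femur", False, 0.0, 0.0, ((0, 0), (0, 1)))
    return ProjectedThicknessMap(
        thickness_mm=t, bone_footprint=fp, pixel_spacing_mm=(0.31, 0.31),
        bone="femur", knee_side="right", canonical=True, alignment=rec, view="distal",
    )


class TestThicknessVolume:
    @pytest.mark.parametrize("n_slices", [3, 5, 8])
    def test_slab_thickness_recovered_within_one_voxel(self, n_slices):
        vol = slab_volume(n_slices)
        dz = vol.spacing_mm[2]
        thick = compute_thickness_volume(vol, FEMUR_BONE, FEMORAL_CARTILAGE)
        interior = thick[10:-10, 10:-10, :]
        vals = interior[np.isfinite(interior)]
        true_mm = n_slices * dz
        assert np.all(np.abs(vals - true_mm) <= dz + 1e-9)

    def test_slab_scaling_linearity(self):
        thin = compute_thickness_volume(slab_volume(3), FEMUR_BONE, FEMORAL_CARTILAGE)
        thick = compute_thickness_volume(slab_volume(6), FEMUR_BONE, FEMORAL_CARTILAGE)
        # doubling voxel count doubles interior (d_bone-dominant) values at
        # matched depth-doubled positions; check the column maxima ratio
        tmax = np.nanmax(thick[20, 20, :])
        nmax = np.nanmax(thin[20, 20, :])
        assert tmax / nmax == pytest.approx(7 / 4, abs=1e-6)  # (6+1)/(3+1)

    def test_isolated_voxel_bounds(self):
        # a single cartilage voxel on bone: d_bone = s, d_ext = s -> 2s; the
        # contract is s <= thickness <= 2s for any spacing-isotropic case
        data = np.zeros((9, 9, 9), np.int16)
        data[:, :, :4] = FEMUR_BONE
        data[4, 4, 4] = FEMORAL_CARTILAGE
        vol = LabelVolume(data=data, spacing_mm=(0.5, 0.5, 0.5), knee_side="right")
        thick = compute_thickness_volume(vol, FEMUR_BONE, FEMORAL_CARTILAGE)
        v = thick[4, 4, 4]
        assert 0.5 <= v <= 1.0 + 1e-9

    def test_cartilage_without_bone_is_an_error(self):
        data = np.zeros((6, 6, 6), np.int16)
        data[2, 2, 2] = FEMORAL_CARTILAGE
        vol = LabelVolume(data=data, spacing_mm=(0.3, 0.3, 0.3), knee_side="right")
        with pytest.raises(ValueError, match="bone"):
            compute_thickness_volume(vol, FEMUR_BONE, FEMORAL_CARTILAGE)


class TestProjection:
    def test_slab_projects_uniform_with_marker_elsewhere(self):
        data = np.zeros((20, 20, 20), np.int16)
        data[:, :, :5] = FEMUR_BONE
        data[5:15, 5:15, 5:8] = FEMORAL_CARTILAGE
        vol = LabelVolume(data=data, spacing_mm=(0.31, 0.31, 0.36), knee_side="right")
        aligned = vol.copy()
        from kneequant.volume import AlignmentRecord
        aligned.alignment["femur"] = AlignmentRecord("femur", False, 0.0, 0.0, ((0, 0), (0, 1)))
        thick = compute_thickness_volume(aligned, FEMUR_BONE, FEMORAL_CARTILAGE)
        pmap = project_thickness(aligned, thick, "femur")
        inner = pmap.thickness_mm[7:13, 7:13]
        assert np.isfinite(inner).all()
        assert np.allclose(inner, inner[0, 0])
        assert np.isnan(pmap.thickness_mm[0, 0])
        assert pmap.bone_footprint.all()

    def test_max_rule_on_stacked_patches(self):
        # two cartilage patches on one ray: pixel takes the larger thickness
        data = np.zeros((10, 10, 30), np.int16)
        data[:, :, :5] = FEMUR_BONE
        data[4, 4, 5:7] = FEMORAL_CARTILAGE      # ~2 voxels
        data[4, 4, 20:25] = FEMORAL_CARTILAGE    # ~5 voxels, detached
        vol = LabelVolume(data=data, spacing_mm=(0.31, 0.31, 0.36), knee_side="right")
        from kneequant.volume import AlignmentRecord
        vol.alignment["femur"] = AlignmentRecord("femur", False, 0.0, 0.0, ((0, 0), (0, 1)))
        thick = compute_thickness_volume(vol, FEMUR_BONE, FEMORAL_CARTILAGE)
        pmap = project_thickness(vol, thick, "femur")
        col = thick[4, 4, :]
        assert pmap.thickness_mm[4, 4] == pytest.approx(np.nanmax(col))

    def test_empty_cartilage_projects_all_markers(self):
        data = np.zeros((10, 10, 20), np.int16)
        data[:, :, :5] = FEMUR_BONE
        data[4, 4, 5] = FEMORAL_CARTILAGE  # needed to compute thickness ...
        vol = LabelVolume(data=data, spacing_mm=(0.31, 0.31, 0.36), knee_side="right")
        from kneequant.volume import AlignmentRecord
        vol.alignment["femur"] = AlignmentRecord("femur", False, 0.0, 0.0, ((0, 0), (0, 1)))
        thick = compute_thickness_volume(vol, FEMUR_BONE, FEMORAL_CARTILAGE)
        vol.data[4, 4, 5] = 0  # ... then remove it: no cartilage anywhere
        pmap = project_thickness(vol, thick, "femur")
        assert np.isnan(pmap.thickness_mm).all()

    def test_requires_alignment_provenance(self, tiny_phantom):
        thick = compute_thickness_volume(tiny_phantom, FEMUR_BONE, FEMORAL_CARTILAGE)
        with pytest.raises(ValueError, match="alignment"):
            project_thickness(tiny_phantom, thick, "femur")


class TestAlignment:
    def test_canonical_phantom_needs_no_rotation(self, tiny_phantom):
        aligned = align_volume(tiny_phantom, "femur")
        rec = aligned.alignment["femur"]
        assert abs(rec.inplane_rotation_deg) < 0.5
        assert rec.long_axis_rotation_deg == 0.0
        assert not rec.mirrored

    def test_empty_femur_is_alignment_error(self):
        data = np.zeros((10, 10, 10), np.int16)
        vol = LabelVolume(data=data, spacing_mm=(0.3, 0.3, 0.3), knee_side="right")
        with pytest.raises(ValueError):
            align_volume(vol, "femur")

    def test_degenerate_bone_mask_rejected(self):
        # a cube has no preferred principal axis (spread ratio ~1)
        data = np.zeros((30, 30, 30), np.int16)
        data[5:25, 5:25, 5:25] = FEMUR_BONE
        data[10, 10, 25] = FEMORAL_CARTILAGE
        vol = LabelVolume(data=data, spacing_mm=(0.3, 0.3, 0.3), knee_side="right")
        with pytest.raises(AlignmentError, match="degenerate"):
            align_volume(vol, "femur")

    def test_left_knee_mirrored_to_canonical(self, tiny_spec, tiny_phantom):
        from dataclasses import replace
        from kneequant.phantom import make_knee_phantom

        left = make_knee_phantom(replace(tiny_spec, knee_side="left"))
        aligned = align_volume(left, "femur")
        assert aligned.alignment["femur"].mirrored
        assert aligned.canonical
        ref = align_volume(tiny_phantom, "femur")
        assert np.array_equal(aligned.data, ref.data)


@pytest.fixture(scope="module")
def fem_map(tiny_phantom):
    aligned = align_volume(tiny_phantom, "femur")
    thick = compute_thickness_volume(aligned, FEMUR_BONE, FEMORAL_CARTILAGE)
    return project_thickness(aligned, thick, "femur")


class TestROIs:
    def test_quadrants_partition_closed_curve_interior(self, fem_map):
        from scipy.ndimage import binary_fill_holes

        rois = define_femoral_rois(fem_map)
        total = sum(r.pixel_count for r in rois.values())
        interior = int(binary_fill_holes(fem_map.bone_footprint).sum())
        assert total == interior
        stack = np.stack([r.mask for r in rois.values()])
        assert (stack.sum(axis=0) <= 1).all()  # pairwise disjoint

    def test_symmetric_footprint_gives_equal_quadrants(self, fem_map):
        rois = define_femoral_rois(fem_map)
        counts = sorted(r.pixel_count for r in rois.values())
        # medial and lateral mirror halves; anterior/posterior split is the
        # bounding-box midline so rows may differ by one
        assert max(counts) - min(counts) <= max(fem_map.bone_footprint.shape)

    def test_disconnected_footprint_rejected(self, fem_map):
        import copy

        broken = copy.deepcopy(fem_map)
        blob = np.zeros_like(broken.bone_footprint)
        blob[:2, :2] = True
        broken.bone_footprint = broken.bone_footprint | blob
        with pytest.raises(ROIError, match="connected"):
            define_femoral_rois(broken)

    def test_mirrored_knees_have_matching_named_regions(self, tiny_spec, tiny_phantom):
        from dataclasses import replace
        from kneequant.phantom import make_knee_phantom

        left = make_knee_phantom(replace(tiny_spec, knee_side="left"))

        def pm_mask(vol):
            aligned = align_volume(vol, "femur")
            thick = compute_thickness_volume(aligned, FEMUR_BONE, FEMORAL_CARTILAGE)
            pmap = project_thickness(aligned, thick, "femur")
            return define_femoral_rois(pmap)["posteromedial"].mask

        assert np.array_equal(pm_mask(left), pm_mask(tiny_phantom))

    def test_tibial_halves_and_one_sided_error(self, tiny_phantom):
        from kneequant.volume import TIBIA_BONE, TIBIAL_CARTILAGE

        aligned = align_volume(tiny_phantom, "tibia")
        thick = compute_thickness_volume(aligned, TIBIA_BONE, TIBIAL_CARTILAGE)
        pmap = project_thickness(aligned, thick, "tibia")
        rois = define_tibial_rois(pmap)
        assert abs(rois["medial"].pixel_count - rois["lateral"].pixel_count) <= \
            pmap.bone_footprint.shape[0]
        import copy

        half = copy.deepcopy(pmap)
        keep = np.nonzero(half.bone_footprint)[1].min()
        # degenerate plateau: all bone in one column, nothing lateral of the
        # midline split -> the lateral ROI cannot be constructed
        half.bone_footprint[:, :] = False
        half.bone_footprint[10:20, keep] = True
        with pytest.raises(ROIError, match="empty"):
            define_tibial_rois(half)


class TestRegionMetrics:
    def test_uniform_cartilage_full_ratio(self):
        pmap = _make_pmap(np.full((10, 10), 2.0))
        from kneequant.geometry import RegionOfInterest

        roi = RegionOfInterest("r", np.ones((10, 10), bool))
        assert projected_area_ratio(pmap, roi, 1.5) == 1.0
        assert mean_region_thickness(pmap, roi) == pytest.approx(2.0)

    def test_absent_cartilage_zero_ratio_and_thickness(self):
        pmap = _make_pmap(np.full((10, 10), np.nan))
        from kneequant.geometry import RegionOfInterest

        roi = RegionOfInterest("r", np.ones((10, 10), bool))
        assert projected_area_ratio(pmap, roi, 1.5) == 0.0
        assert mean_region_thickness(pmap, roi) == 0.0

    def test_half_coverage_averaging_convention(self):
        t = np.full((10, 10), np.nan)
        t[:5] = 2.0
        pmap = _make_pmap(t)
        from kneequant.geometry import RegionOfInterest

        roi = RegionOfInterest("r", np.ones((10, 10), bool))
        # no-cartilage pixels count as 0 mm in the mean
        assert mean_region_thickness(pmap, roi) == pytest.approx(1.0)

    def test_threshold_inclusive_and_monotone(self):
        t = np.tile(np.linspace(0.5, 3.0, 26), (4, 1))
        pmap = _make_pmap(t)
        from kneequant.geometry import RegionOfInterest

        roi = RegionOfInterest("r", np.ones_like(t, bool))
        exactly = projected_area_ratio(pmap, roi, 1.5)
        assert exactly == pytest.approx(np.mean(t >= 1.5))
        ratios = [projected_area_ratio(pmap, roi, th) for th in np.linspace(0, 3.5, 15)]
        assert all(a >= b - 1e-12 for a, b in zip(ratios, ratios[1:]))
        assert all(0.0 <= r <= 1.0 for r in ratios)

    def test_empty_roi_rejected(self):
        from kneequant.geometry import RegionOfInterest

        with pytest.raises(ROIError):
            RegionOfInterest("r", np.zeros((5, 5), bool))


class TestDice:
    def test_anchor_values(self):
        a = np.zeros((8, 8), bool)
        a[:4] = True
        assert dice_coefficient(a, a) == 1.0
        assert dice_coefficient(a, ~a) == 0.0
        b = np.zeros((8, 8), bool)
        b[2:6] = True  # equal size, half overlap
        assert dice_coefficient(a, b) == 0.5

    def test_empty_masks_define_one(self):
        z = np.zeros((4, 4), bool)
        assert dice_coefficient(z, z) == 1.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            dice_coefficient(np.ones((3, 3), bool), np.ones((4, 4), bool))


class TestRendering:
    def test_color_anchors_bit_exact(self):
        t = np.array([[2.5, np.nan, 1.0, 0.0]])
        pmap = _make_pmap(t)
        img = render_thickness_map(pmap)
        assert tuple(img[0, 0]) == (1.0, 1.0, 1.0)   # > 2 mm: white
        assert tuple(img[0, 1]) == (0.5, 0.5, 0.5)   # no cartilage: gray
        assert tuple(img[0, 2]) == (1.0, 0.5, 0.5)   # 1 mm: ramp midpoint
        assert tuple(img[0, 3]) == (1.0, 0.0, 0.0)   # 0 mm: pure red
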