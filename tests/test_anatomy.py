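"""Filled bone, end plateau, axis fit, peels, and ROI generation."""

import numpy as np
import pytest

from bonemicrokit import anatomy
from bonemicrokit.anatomy import (
    AxisFitError,
    EmptyRoiError,
    PlateauNotFoundError,
    RoiMask,
    SamplingError,
    compute_peel,
    fill_bone_volume,
    fit_tibial_axis,
    locate_end_plateau,
    make_axial_roi,
    sample_spherical_rois,
    sphere_mask,
)
from bonemicrokit.volume import ConfigurationError, DensityVolume, Units

SP = 0.15


def _vol(values):
    return DensityVolume(values, (SP,) * 3, units=Units.MG_CC)


def _cylinder(outer_r_mm, wall_mm, nz=60, pad_mm=1.0, spacing=SP):
    n = int(round(2 * (outer_r_mm + pad_mm) / spacing))
    c = (n - 1) / 2 * spacing
    yy, xx = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing, indexing="ij")
    rr = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
    ring = (rr <= outer_r_mm) & (rr > outer_r_mm - wall_mm)
    vals = np.where(ring, 1200.0, 50.0)
    return _vol(np.tile(vals[None], (nz, 1, 1)))


class TestFillBone:
    def test_hollow_cylinder_fills_to_analytic_volume(self):
        v = _cylinder(outer_r_mm=3.0, wall_mm=0.6, nz=40)
        filled = fill_bone_volume(v, bone_threshold=300.0)
        analytic = np.pi * 3.0**2 * (40 * SP) / SP**3
        assert filled.count == pytest.approx(analytic, rel=0.02)

    def test_solid_cube_unchanged(self):
        vals = np.full((20, 20, 20), 50.0)
        vals[5:15, 5:15, 5:15] = 900.0
        filled = fill_bone_volume(_vol(vals), bone_threshold=300.0, closing_radii_mm=(0.3,))
        assert filled.count == 1000

    def test_largest_of_two_bones_retained(self):
        vals = np.full((20, 30, 20), 50.0)
        vals[5:15, 2:12, 5:15] = 900.0   # 10x10x10
        vals[5:10, 20:25, 5:10] = 900.0  # 5x5x5
        filled = fill_bone_volume(_vol(vals), bone_threshold=300.0, closing_radii_mm=(0.3,))
        assert filled.voxels[7, 22, 7] == False  # noqa: E712
        assert filled.voxels[7, 7, 7]


class TestEndPlateau:
    def test_tibia_phantom_plateau_matches_truth(self, tibia_untilted):
        vol, gt = tibia_untilted
        filled = fill_bone_volume(vol)
        assert locate_end_plateau(filled) == gt.plateau_slice

    def test_solid_cylinder_has_no_plateau(self):
        vals = np.full((30, 20, 20), 50.0)
        vals[:, 5:15, 5:15] = 900.0
        filled = fill_bone_volume(_vol(vals), closing_radii_mm=(0.3,))
        with pytest.raises(PlateauNotFoundError):
            locate_end_plateau(filled)

    def test_hole_at_first_traced_slice_clamps_to_boundary(self):
        # annular ring only at the topmost (most proximal) slice
        vals = np.full((10, 30, 30), 50.0)
        yy, xx = np.meshgrid(np.arange(30), np.arange(30), indexing="ij")
        rr = np.sqrt((yy - 14.5) ** 2 + (xx - 14.5) ** 2)
        ring = (rr <= 12) & (rr > 8)
        vals[9][ring] = 1200.0
        vals[0:9, 5:25, 5:25] = 1200.0  # solid below so the mask is connected enough
        mask = RoiMask(vals >= 300.0, (SP,) * 3)
        assert locate_end_plateau(mask) == 9


class TestPeel:
    def _disk_mask(self, radius_vox=20, n=45, nz=3):
        yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        disk = (yy - n // 2) ** 2 + (xx - n // 2) ** 2 <= radius_vox**2
        return RoiMask(np.tile(disk[None], (nz, 1, 1)), (SP,) * 3)

    def test_zero_peel_is_identity(self):
        m = self._disk_mask()
        assert (compute_peel(m, 0.0).voxels == m.voxels).all()

    def test_full_peel_keeps_only_maxima(self):
        m = self._disk_mask()
        peeled = compute_peel(m, 100.0)
        assert 0 < peeled.count <= 3 * 9  # at most a few voxels per slice

    def test_disk_area_ratio_matches_analytic(self):
        m = self._disk_mask(radius_vox=20)
        peeled = compute_peel(m, 60.0)
        # retained region is approximately the disk of radius 0.4 R
        ratio = peeled.count / m.count
        assert ratio == pytest.approx(0.16, abs=0.03)

    def test_monotone_in_peel_percent(self):
        m = self._disk_mask()
        p30 = compute_peel(m, 30.0)
        p60 = compute_peel(m, 60.0)
        assert (p60.voxels <= p30.voxels).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ConfigurationError):
            compute_peel(self._disk_mask(), 120.0)


class TestAxisFit:
    def test_axis_aligned_cylinder_gives_z(self):
        v = _cylinder(outer_r_mm=3.0, wall_mm=3.0, nz=100)
        filled = fill_bone_volume(v, closing_radii_mm=(0.3,))
        frame = fit_tibial_axis(filled, plateau_slice=0, tibial_length_mm=20.0)
        np.testing.assert_allclose(frame.axis_direction, [1, 0, 0], atol=1e-6)

    def test_tilted_phantom_axis_recovered_within_one_degree(self, tibia_run_pair):
        out, gt = tibia_run_pair["tilted"]
        # the pipeline re-fits after realignment; initial tilt is logged
        assert out["provenance"]["initial_axis_tilt_deg"] == pytest.approx(10.0, abs=1.0)

    def test_too_few_slices_raises(self):
        v = _cylinder(outer_r_mm=3.0, wall_mm=3.0, nz=20)
        filled = fill_bone_volume(v, closing_radii_mm=(0.3,))
        with pytest.raises(AxisFitError):
            fit_tibial_axis(filled, plateau_slice=0, tibial_length_mm=100.0)


class TestAxialRoi:
    @pytest.fixture(scope="class")
    def frame_and_filled(self, tibia_untilted):
        vol, gt = tibia_untilted
        filled = fill_bone_volume(vol)
        plateau = locate_end_plateau(filled)
        frame = fit_tibial_axis(filled, plateau, 100.0)
        return frame, filled

    def test_site_slab_arithmetic(self, frame_and_filled):
        frame, filled = frame_and_filled
        roi = make_axial_roi(frame, filled, (4, 6), peel=None)
        zs = np.where(roi.voxels.any(axis=(1, 2)))[0]
        # 4% and 6% of 100 mm at 0.15 mm slices from the plateau
        assert zs.min() == frame.plateau_slice + int(np.ceil(4.0 / 100 * 100 / SP))
        assert zs.max() == frame.plateau_slice + int(np.floor(6.0 / 100 * 100 / SP))

    def test_inner_outer_disjoint_and_nested(self, frame_and_filled):
        frame, filled = frame_and_filled
        inner = make_axial_roi(frame, filled, (4, 6), peel="inner60")
        outer = make_axial_roi(frame, filled, (4, 6), peel="annulus30-60")
        assert not (inner.voxels & outer.voxels).any()
        p30 = compute_peel(filled, 30.0)
        assert (inner.voxels <= p30.voxels).all()
        assert (outer.voxels <= p30.voxels).all()

    def test_cortical_band_site(self, frame_and_filled):
        frame, filled = frame_and_filled
        band = make_axial_roi(frame, filled, (14, 16), peel=None)
        assert band.count > 0 and band.site_range_pct == (14, 16)

    def test_empty_roi_raises(self, frame_and_filled):
        frame, filled = frame_and_filled
        empty = RoiMask(np.zeros_like(filled.voxels), filled.spacing)
        with pytest.raises(EmptyRoiError):
            make_axial_roi(frame, empty, (4, 6), peel=None)


class TestSphericalRois:
    def test_sphere_diameter_spans_47_voxels(self):
        mask = sphere_mask((61, 61, 61), (0.15,) * 3, (30, 30, 30), 7.05)
        zs = np.where(mask.any(axis=(1, 2)))[0]
        assert zs.max() - zs.min() + 1 == 47

    def test_zero_spheres_and_determinism(self):
        region = RoiMask(np.ones((60, 60, 60), bool), (0.15,) * 3)
        assert sample_spherical_rois(region, 0, 5.0, seed=1) == []
        a = sample_spherical_rois(region, 3, 5.0, seed=7)
        b = sample_spherical_rois(region, 3, 5.0, seed=7)
        for r1, r2 in zip(a, b):
            assert (r1.voxels == r2.voxels).all()

    def test_spheres_inside_region(self):
        region = RoiMask(np.ones((60, 60, 60), bool), (0.15,) * 3)
        for roi in sample_spherical_rois(region, 4, 6.0, seed=3):
            assert (roi.voxels <= region.voxels).all()

    def test_infeasible_packing_raises(self):
        region = RoiMask(np.ones((10, 10, 10), bool), (0.15,) * 3)
        with pytest.raises(SamplingError):
            sample_spherical_rois(region, 1, 7.05, seed=0)
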