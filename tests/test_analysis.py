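"""Dose-grid measurements: peaks, shifts, fits, isodose circles, FWHM scans."""

import math

import numpy as np
import pytest
from scipy import stats

import braggshift as bs
from braggshift.analysis import (
    PlanarSlab,
    _depth_and_lateral_peak,
    fit_ic_ec,
    fwhm_scan,
    isodose_contour,
)
from braggshift.errors import ContourError, IncompatibleGridsError, NoPeakError
from braggshift.simulate import DoseGrid, PhantomGrid

FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


def small_grid(extent=(4.0, 4.0, 4.0), voxel=(0.1, 0.1, 0.1), origin=(-2.0, -2.0, 0.0)):
    return PhantomGrid(extent=extent, voxel=voxel, origin=origin)


def gaussian_grid(center, sigmas, grid=None, rotation_xz_deg=0.0):
    """3D Gaussian dose grid, optionally rotated in the bending (x-z) plane."""
    grid = grid or small_grid()
    x, y, z = np.meshgrid(
        grid.axis_centers(0), grid.axis_centers(1), grid.axis_centers(2), indexing="ij"
    )
    dx, dy, dz = x - center[0], y - center[1], z - center[2]
    a = math.radians(rotation_xz_deg)
    xr = dx * math.cos(a) - dz * math.sin(a)
    zr = dx * math.sin(a) + dz * math.cos(a)
    vals = np.exp(
        -(xr**2 / (2 * sigmas[0] ** 2) + dy**2 / (2 * sigmas[1] ** 2)
          + zr**2 / (2 * sigmas[2] ** 2))
    ).astype(np.float32)
    return DoseGrid(values=vals, grid=grid, provenance={"field_t": 0.0})


class TestFindBraggPeak:
    def test_single_voxel(self):
        grid = small_grid()
        vals = np.zeros(grid.shape, dtype=np.float32)
        vals[10, 20, 30] = 1.0
        peak = bs.find_bragg_peak(DoseGrid(values=vals, grid=grid, provenance={}))
        assert peak.x == pytest.approx(grid.axis_centers(0)[10])
        assert peak.y == pytest.approx(grid.axis_centers(1)[20])
        assert peak.z == pytest.approx(grid.axis_centers(2)[30])

    def test_subvoxel_refinement_of_offset_gaussian(self):
        dose = gaussian_grid((0.13, -0.22, 2.04), (0.4, 0.4, 0.3))
        peak = bs.find_bragg_peak(dose)
        assert peak.x == pytest.approx(0.13, abs=0.01)
        assert peak.y == pytest.approx(-0.22, abs=0.01)
        assert peak.z == pytest.approx(2.04, abs=0.01)

    def test_all_zero_rejected(self):
        grid = small_grid()
        dose = DoseGrid(values=np.zeros(grid.shape, np.float32), grid=grid, provenance={})
        with pytest.raises(NoPeakError):
            bs.find_bragg_peak(dose)

    def test_pencil_peak_depth_close_to_range(self, pencil_grid_100_b0):
        z, _, _ = _depth_and_lateral_peak(pencil_grid_100_b0)
        total_range = bs.range_from_energy(100.0)
        sig_r = 0.012 * total_range**0.935
        assert total_range - 2.5 * sig_r < z <= total_range


class TestMeasureShifts:
    def test_identical_grids_zero_shift(self, pencil_grid_100_b0):
        sm = bs.measure_shifts(pencil_grid_100_b0, pencil_grid_100_b0)
        assert sm.wd == 0.0 and sm.ddd == 0.0 and sm.angle_def == 0.0

    def test_mismatched_energy_rejected(self, coarse_grid, pencil_grid_100_b0):
        other = bs.simulate_dose_grid(bs.BeamSpec(120.0), bs.FieldSpec(0.0), coarse_grid)
        with pytest.raises(IncompatibleGridsError):
            bs.measure_shifts(other, pencil_grid_100_b0)

    def test_nonzero_field_reference_rejected(self, coarse_grid):
        g = bs.simulate_dose_grid(bs.BeamSpec(100.0), bs.FieldSpec(1.0), coarse_grid)
        with pytest.raises(IncompatibleGridsError):
            bs.measure_shifts(g, g)

    @pytest.mark.parametrize("energy, field", [(100.0, 3.0), (141.0, 3.0), (170.0, 1.5)])
    def test_pencil_grids_reproduce_analytic_model(self, coarse_grid, energy, field):
        """Non-relativistic pencil grids match the closed forms: WD within 5%,
        dDD within max(5%, 0.3 depth-voxel) -- sub-voxel retractions cannot be
        localized more finely from 1 mm slabs."""
        ref = bs.simulate_dose_grid(
            bs.BeamSpec(energy), bs.FieldSpec(0.0), coarse_grid, relativistic=False
        )
        dose = bs.simulate_dose_grid(
            bs.BeamSpec(energy), bs.FieldSpec(field), coarse_grid, relativistic=False
        )
        sm = bs.measure_shifts(dose, ref)
        wd_ref = bs.lateral_shift(energy, field)
        ddd_ref = bs.depth_retraction(energy, field)
        assert sm.wd == pytest.approx(wd_ref, rel=0.05)
        assert abs(sm.ddd - ddd_ref) <= max(0.05 * ddd_ref, 0.3 * coarse_grid.voxel[2])
        assert sm.angle_def == pytest.approx(
            math.degrees(math.atan2(sm.wd, sm.reference_peak_depth - sm.ddd)), abs=0.2
        )


class TestDepthDoseCurve:
    def test_uniform_grid_flat_profile(self):
        grid = small_grid()
        dose = DoseGrid(values=np.ones(grid.shape, np.float32), grid=grid, provenance={})
        _, prof = bs.depth_dose_curve(dose, normalization="surface")
        assert np.allclose(prof, 1.0)

    def test_peak_consistent_with_bragg_peak(self, pencil_grid_100_b0):
        z, prof = bs.depth_dose_curve(pencil_grid_100_b0, normalization="max")
        peak = bs.find_bragg_peak(pencil_grid_100_b0)
        assert abs(z[np.argmax(prof)] - peak.z) <= 2 * pencil_grid_100_b0.grid.voxel[2]

    def test_zero_entrance_rejected(self):
        grid = small_grid()
        vals = np.zeros(grid.shape, np.float32)
        vals[:, :, 20] = 1.0
        with pytest.raises(ValueError):
            bs.depth_dose_curve(DoseGrid(values=vals, grid=grid, provenance={}))


class TestGaussianFit:
    def test_exact_recovery(self):
        x = np.linspace(-3, 3, 121)
        y = 2.0 * np.exp(-((x - 0.3) ** 2) / (2 * 0.5**2))
        fit = bs.fit_gaussian_1d(x, y)
        assert fit.sigma == pytest.approx(0.5, abs=1e-6)
        assert fit.mean == pytest.approx(0.3, abs=1e-6)
        assert fit.rms_residual < 1e-9
        assert fit.halfwidth_asymmetry == pytest.approx(0.0, abs=1e-6)

    def test_skewed_profile_has_positive_asymmetry(self):
        x = np.linspace(-3, 5, 300)
        y = stats.skewnorm.pdf(x, 4)
        fit = bs.fit_gaussian_1d(x, y)
        assert fit.halfwidth_asymmetry > 0.01

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            bs.fit_gaussian_1d(np.arange(3.0), np.ones(3))


class TestPlanarAndSigmaRatio:
    def test_slab_maximum_at_center(self, gaussian_slab_builder):
        slab = gaussian_slab_builder(0.6, 0.6)
        iu, iv = np.unravel_index(np.argmax(slab.values), slab.values.shape)
        assert abs(slab.u[iu]) < slab.pixel[0]
        assert abs(slab.v[iv]) < slab.pixel[1]
        assert slab.values.max() == pytest.approx(1.0, rel=1e-6)

    def test_isotropic_ratio_is_one(self, gaussian_slab_builder):
        assert bs.sigma_ratio(gaussian_slab_builder(0.6, 0.6)) == pytest.approx(
            1.0, abs=0.01
        )

    def test_elliptical_ratio_recovered(self, gaussian_slab_builder):
        slab = gaussian_slab_builder(0.78, 0.6)
        assert bs.sigma_ratio(slab) == pytest.approx(1.3, abs=0.01)
        assert bs.sigma_ratio(slab, profiles="central") == pytest.approx(1.3, abs=0.01)

    def test_planar_at_peak_of_symmetric_grid(self):
        dose = gaussian_grid((0.0, 0.0, 2.0), (0.5, 0.5, 0.3))
        slab = bs.planar_at_peak(dose)
        assert slab.values.max() == pytest.approx(1.0)
        assert bs.sigma_ratio(slab) == pytest.approx(1.0, abs=0.01)


class TestIsodose:
    def test_circular_gaussian_contour_radius(self, gaussian_slab_builder):
        sigma = 0.7
        slab = gaussian_slab_builder(sigma, sigma)
        fit = fit_ic_ec(isodose_contour(slab, 0.5), 0.5)
        assert fit.mean_radius == pytest.approx(sigma * math.sqrt(2 * math.log(2)),
                                                abs=slab.pixel[0])
        assert fit.radius_diff < slab.pixel[0] / 2

    def test_nested_levels(self, gaussian_slab_builder):
        slab = gaussian_slab_builder(0.7, 0.5)
        radii = [
            fit_ic_ec(isodose_contour(slab, lvl), lvl).mean_radius
            for lvl in (0.8, 0.5, 0.2)
        ]
        assert radii[0] < radii[1] < radii[2]

    def test_elliptical_axis_ratio(self, gaussian_slab_builder):
        slab = gaussian_slab_builder(0.78, 0.6)
        fit = fit_ic_ec(isodose_contour(slab, 0.5), 0.5)
        assert fit.r_ec / fit.r_ic == pytest.approx(1.3, rel=0.02)

    def test_invalid_level_rejected(self, gaussian_slab_builder):
        slab = gaussian_slab_builder(0.6, 0.6)
        with pytest.raises(ValueError):
            isodose_contour(slab, 1.5)

    def test_open_contour_rejected(self, gaussian_slab_builder):
        slab = gaussian_slab_builder(3.0, 1.0, extent=4.0)  # long axis exits the slab
        with pytest.raises(ContourError):
            isodose_contour(slab, 0.5)


class TestIcEc:
    def test_exact_circle(self):
        t = np.linspace(0, 2 * np.pi, 256)
        fit = fit_ic_ec(np.c_[3 * np.cos(t) + 1.0, 3 * np.sin(t) - 2.0])
        assert fit.r_ic == pytest.approx(3.0, abs=1e-3)
        assert fit.r_ec == pytest.approx(3.0, abs=1e-3)
        assert fit.center[0] == pytest.approx(1.0, abs=1e-3)
        assert fit.center[1] == pytest.approx(-2.0, abs=1e-3)

    def test_axis_aligned_ellipse(self):
        t = np.linspace(0, 2 * np.pi, 512)
        fit = fit_ic_ec(np.c_[4 * np.cos(t), 2 * np.sin(t)])
        assert fit.r_ic == pytest.approx(2.0, abs=1e-3)
        assert fit.r_ec == pytest.approx(4.0, abs=1e-3)

    def test_rotation_and_translation_invariance(self):
        t = np.linspace(0, 2 * np.pi, 512)
        ellipse = np.c_[4 * np.cos(t), 2 * np.sin(t)]
        phi = math.radians(30)
        rot = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
        moved = ellipse @ rot.T + np.array([0.7, -1.1])
        a = fit_ic_ec(ellipse)
        b = fit_ic_ec(moved)
        assert b.r_ic == pytest.approx(a.r_ic, abs=1e-3)
        assert b.r_ec == pytest.approx(a.r_ec, abs=1e-3)

    def test_degenerate_contour_rejected(self):
        line = np.c_[np.linspace(0, 1, 50), np.zeros(50)]
        with pytest.raises(ContourError):
            fit_ic_ec(line)


class TestSkewnessByLevel:
    def test_identical_slabs_give_equal_pairs(self, gaussian_slab_builder):
        slab = gaussian_slab_builder(0.7, 0.6)
        table = bs.skewness_by_level(slab, gaussian_slab_builder(0.7, 0.6))
        assert np.allclose(table.radius_diff_field, table.radius_diff_nofield, atol=1e-6)

    def test_radius_diff_grows_with_standard_radius(self, gaussian_slab_builder):
        # elliptical level sets: radius difference scales with contour size,
        # so lower dose levels (larger standard radius) show larger skewness
        table = bs.skewness_by_level(
            gaussian_slab_builder(0.72, 0.6), gaussian_slab_builder(0.6, 0.6)
        )
        assert table.standard_radius.is_monotonic_increasing
        diffs = table.radius_diff_field.to_numpy()
        assert diffs[0] < diffs[1] < diffs[2]


class TestFwhmScan:
    def test_isotropic_gaussian_constant_fwhm(self):
        sigma = 0.5
        dose = gaussian_grid((0.0, 0.0, 2.0), (sigma, sigma, sigma))
        scan = fwhm_scan(dose, angle_step=5.0)
        assert np.all(np.abs(scan.fwhm - FWHM * sigma) / (FWHM * sigma) < 0.01)

    def test_rotated_principal_axis_recovered(self):
        grid = small_grid(extent=(10.0, 10.0, 10.0), origin=(-5.0, -5.0, 0.0))
        dose = gaussian_grid((0.0, 0.0, 5.0), (0.4, 0.4, 1.0), grid=grid,
                             rotation_xz_deg=25.0)
        scan = fwhm_scan(dose, angle_step=1.0)
        assert scan.angle_max == pytest.approx(25.0, abs=1.0)
        assert scan.fwhm_max == pytest.approx(FWHM * 1.0, rel=0.01)
        assert scan.fwhm_min == pytest.approx(FWHM * 0.4, rel=0.01)
        assert scan.angle_min == pytest.approx(115.0, abs=1.0)

    def test_vertical_is_zero_degree_line(self):
        dose = gaussian_grid((0.0, 0.0, 2.0), (0.4, 0.4, 0.6))
        scan = fwhm_scan(dose, angle_step=2.0)
        assert scan.fwhm_vertical == scan.fwhm[0]
        assert scan.fwhm_min <= scan.fwhm_vertical <= scan.fwhm_max

    def test_invalid_angle_step_rejected(self):
        dose = gaussian_grid((0.0, 0.0, 2.0), (0.4, 0.4, 0.4))
        with pytest.raises(ValueError):
            fwhm_scan(dose, angle_step=0.0)
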