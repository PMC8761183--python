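"""Concentration metrics, ROI volumes, recovery coefficients, CNR/SNR."""

import numpy as np
import pytest

from petquant.grid import ActivityImage, VoxelGrid
from petquant.phantom import (
    Box,
    CompartmentSpec,
    Cylinder,
    LesionSpec,
    PhantomSpec,
    build_phantom,
    sphere_volume_ml,
)
from petquant.projector import psf_blur
from petquant.quantitation import (
    ClippedROIError,
    contrast_and_noise,
    ground_truth_from_cold_scan,
    measure_apex,
    measure_lesion,
    measure_max,
    measure_mean,
    measure_peak,
    mtv,
    recovery_coefficient,
    spherical_roi,
    ttu,
)
from petquant.segmentation import SeedPoint, segment_fixed_threshold


@pytest.fixture(scope="module")
def grid():
    return VoxelGrid.centered((32, 32, 16))


class TestRoiVolumes:
    @pytest.mark.parametrize("volume", [0.26, 1.0, 0.5])
    def test_fractional_roi_reproduces_nominal_volume(self, grid, volume):
        w = spherical_roi(grid, (1.0, 0.5, -0.3), volume)
        assert w.sum() * grid.voxel_volume == pytest.approx(volume, rel=1e-6)
        assert w.min() >= 0.0 and w.max() <= 1.0

    def test_one_ml_roi_equivalent_diameter(self):
        # closed form: d = 2·(3V/4π)^(1/3) = 12.4 mm for 1 mL
        d = 2.0 * (3.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        assert d == pytest.approx(12.407, abs=1e-3)

    def test_apex_roi_spans_about_six_default_voxels(self, grid):
        w = spherical_roi(grid, (0, 0, 0), 0.26)
        assert 0.26 / grid.voxel_volume == pytest.approx(6.0, rel=0.01)

    def test_clipped_roi_raises(self, grid):
        with pytest.raises(ClippedROIError):
            spherical_roi(grid, (55.0, 55.0, 0.0), 1.0)


class TestMeasures:
    def test_uniform_region_all_metrics_agree(self, grid):
        img = ActivityImage(grid=grid, values=np.full(grid.shape, 4.2))
        mask = np.zeros(grid.shape)
        mask[10:20, 10:20, 4:10] = 1.0
        assert measure_max(img, mask) == 4.2
        assert measure_mean(img, mask) == pytest.approx(4.2)
        assert measure_peak(img, mask) == pytest.approx(4.2)
        assert measure_apex(img, mask) == pytest.approx(4.2)

    def test_weighted_mean_arithmetic(self, grid):
        img_vals = np.zeros(grid.shape)
        img_vals[0, 0, 0], img_vals[0, 0, 1] = 10.0, 4.0
        w = np.zeros(grid.shape)
        w[0, 0, 0], w[0, 0, 1] = 1.0, 0.5
        img = ActivityImage(grid=grid, values=img_vals)
        assert measure_mean(img, w) == pytest.approx(8.0)

    def test_empty_mask_rejected(self, grid):
        img = ActivityImage(grid=grid, values=np.ones(grid.shape))
        with pytest.raises(ValueError):
            measure_mean(img, np.zeros(grid.shape))

    def test_point_lesion_peak_much_smaller_than_max(self, grid):
        # an isolated hot voxel dilutes into the 1-mL peak ROI by ~vox/1mL
        vals = np.zeros(grid.shape)
        vals[16, 16, 8] = 100.0
        img = ActivityImage(grid=grid, values=vals)
        peak = measure_peak(img)
        assert peak < 0.1 * measure_max(img, vals > 0)
        assert peak == pytest.approx(100.0 * grid.voxel_volume / 1.0, rel=0.3)

    def test_apex_between_peak_and_max_for_small_lesion(self, grid):
        spec = PhantomSpec(
            grid=grid,
            compartments=[CompartmentSpec("b", Box((0, 0, 0), tuple(grid.extent)), 0.0)],
            lesions=[LesionSpec("l", (0.5, 0.5, 0.5), 8.0, 57.6)],
        )
        img = build_phantom(spec)
        support = img.values > 0
        a_max = measure_max(img, support)
        a_peak = measure_peak(img)
        a_apex = measure_apex(img)
        assert a_max >= a_apex >= a_peak
        # 8-mm lesion (0.268 mL): apex ROI (0.26 mL) ~ lesion, peak (1 mL) dilutes
        assert a_apex > 1.5 * a_peak


class TestVolumesAndRecovery:
    def test_mtv_and_ttu_identities(self, grid):
        img = ActivityImage(grid=grid, values=np.full(grid.shape, 7.0))
        spec = PhantomSpec(
            grid=grid,
            compartments=[CompartmentSpec("b", Box((0, 0, 0), tuple(grid.extent)), 1.0)],
            lesions=[LesionSpec("l", (0, 0, 0), 12.0, 30.0)],
        )
        mask = segment_fixed_threshold(build_phantom(spec), SeedPoint((0, 0, 0)))
        vol = mtv(mask)
        assert vol == pytest.approx(mask.weights.sum() * grid.voxel_volume)
        assert ttu(10.0, 0.5) == 5.0
        assert ttu(measure_mean(img, mask.weights), vol) == measure_mean(img, mask.weights) * vol

    @pytest.mark.parametrize("meas,true,expected", [(57.6, 57.6, 100.0), (28.8, 57.6, 50.0), (0.0, 57.6, 0.0)])
    def test_recovery_coefficient(self, meas, true, expected):
        assert recovery_coefficient(meas, true) == pytest.approx(expected)

    def test_recovery_requires_positive_truth(self):
        with pytest.raises(ValueError):
            recovery_coefficient(1.0, 0.0)


class TestGroundTruth:
    def _cold_image(self, grid, diameter=10.0, conc=57.6):
        spec = PhantomSpec(
            grid=grid,
            compartments=[CompartmentSpec("b", Box((0, 0, 0), tuple(grid.extent)), 0.0)],
            lesions=[LesionSpec("l", (0, 0, 0), diameter, conc)],
        )
        return build_phantom(spec)

    def test_ideal_cold_scan_recovers_cast_concentration(self, grid):
        cold = self._cold_image(grid)
        gt = ground_truth_from_cold_scan(cold, (0, 0, 0), sphere_volume_ml(10.0))
        assert gt.a_true == pytest.approx(57.6, rel=5e-3)

    def test_blur_invariance_of_ground_truth(self, grid):
        cold = self._cold_image(grid)
        gt0 = ground_truth_from_cold_scan(cold, (0, 0, 0), sphere_volume_ml(10.0))
        gt1 = ground_truth_from_cold_scan(psf_blur(cold, 4.7), (0, 0, 0), sphere_volume_ml(10.0))
        assert gt1.a_true == pytest.approx(gt0.a_true, rel=5e-3)

    def test_rc_of_ground_truth_round_trips_to_100(self, grid):
        cold = self._cold_image(grid)
        gt = ground_truth_from_cold_scan(cold, (0, 0, 0), sphere_volume_ml(10.0))
        total = (cold.values.sum() * grid.voxel_volume) / sphere_volume_ml(10.0)
        assert recovery_coefficient(total, gt.a_true) == pytest.approx(100.0, abs=1e-9)

    def test_overlapping_rois_warn(self, grid):
        cold = self._cold_image(grid)
        with pytest.warns(UserWarning, match="overlap"):
            ground_truth_from_cold_scan(
                cold, (0, 0, 0), 0.5, other_lesion_centers=[(20.0, 0.0, 0.0)]
            )


class TestContrastNoise:
    @pytest.fixture()
    def noisy_bkg_image(self, grid):
        spec = PhantomSpec(
            grid=grid,
            compartments=[
                CompartmentSpec("b", Cylinder((0, 0, 0), (55, 55), grid.extent[2]), 1.8)
            ],
        )
        img = build_phantom(spec)
        rng = np.random.default_rng(4)
        vals = img.values * rng.normal(1.0, 0.08, grid.shape).clip(0.3)
        return ActivityImage(grid=grid, values=vals)

    CENTERS = [(30, 0, -15), (-30, 0, -15), (0, 30, -15), (0, -30, -15), (25, 25, 15)]

    def test_snr_minus_cnr_identity(self, noisy_bkg_image):
        cn = contrast_and_noise(noisy_bkg_image, 57.6, 30.0, self.CENTERS)
        ratio = cn.a_bkg / cn.sigma_bkg
        assert cn.SNR_max - cn.CNR_max == pytest.approx(ratio, rel=1e-9)
        assert cn.SNR_mean - cn.CNR_mean == pytest.approx(ratio, rel=1e-9)

    def test_contrast_arithmetic_32_to_1(self, noisy_bkg_image):
        cn = contrast_and_noise(noisy_bkg_image, 57.6, 30.0, self.CENTERS)
        assert cn.C_max == pytest.approx(57.6 / cn.a_bkg * 100.0)

    def test_null_contrast_gives_zero_cnr(self, noisy_bkg_image):
        cn = contrast_and_noise(noisy_bkg_image, 1.0, 1.0, self.CENTERS)
        assert cn.CNR_max == pytest.approx((1.0 - cn.a_bkg) / cn.sigma_bkg)

    def test_roi_lesion_overlap_rejected(self, noisy_bkg_image, grid):
        support = np.zeros(grid.shape, dtype=bool)
        support[24:28, 14:18, 2:6] = True  # under ROI at (30, 0, -15)
        with pytest.raises(ValueError, match="intersects"):
            contrast_and_noise(noisy_bkg_image, 57.6, 30.0, self.CENTERS, lesion_support=support)

    def test_overlapping_background_rois_rejected(self, noisy_bkg_image):
        centers = [(30, 0, -15), (31, 0, -15), (0, 30, -15), (0, -30, -15), (25, 25, 15)]
        with pytest.raises(ValueError, match="overlap"):
            contrast_and_noise(noisy_bkg_image, 57.6, 30.0, centers)


class TestMeasureLesion:
    def test_bundle_consistency(self, grid):
        spec = PhantomSpec(
            grid=grid,
            compartments=[CompartmentSpec("b", Box((0, 0, 0), tuple(grid.extent)), 1.8)],
            lesions=[LesionSpec("l", (0, 0, 0), 14.0, 57.6)],
        )
        img = build_phantom(spec)
        mask = segment_fixed_threshold(img, SeedPoint((0, 0, 0)))
        cold_spec = PhantomSpec(
            grid=grid,
            compartments=[CompartmentSpec("b", Box((0, 0, 0), tuple(grid.extent)), 0.0)],
            lesions=list(spec.lesions),
        )
        gt = ground_truth_from_cold_scan(
            build_phantom(cold_spec), (0, 0, 0), sphere_volume_ml(14.0), "l"
        )
        m = measure_lesion(img, mask, gt)
        assert m.TTU == m.a_mean * m.MTV
        assert m.a_max >= m.a_mean
        assert m.RC_max == pytest.approx(recovery_coefficient(m.a_max, gt.a_true))
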