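"""RP detection, calibration, offset mapping, precision budget, spot fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibtarget import (
    MillingGeometry,
    ProjectedImage,
    calibrate,
    detect_rp,
    locate_spot,
    localization_precision,
    map_to_fib,
    measure_offset,
    nominal_pixel_nm,
    project_point,
    render_fib_view,
)
from fibtarget.registration import (
    CalibrationResult,
    RPDetectionError,
    SpotNotFoundError,
    TargetRecord,
)
from fibtarget.scene import ReferencePatternSpec, random_scene
from fibtarget._rng import substream

from conftest import gaussian_spot_image


def _cross_image(
    spec: ReferencePatternSpec,
    shape: tuple[int, int],
    center_px: tuple[float, float],
    pixel_um: float,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ProjectedImage:
    """Surface-view cross rendered independently of the template code."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    x_um = (xx - center_px[0]) * pixel_um
    y_um = (yy - center_px[1]) * pixel_um
    centered = ReferencePatternSpec(
        center_um=(0.0, 0.0),
        arm_length_um=spec.arm_length_um,
        arm_width_um=spec.arm_width_um,
        depth_contrast=spec.depth_contrast,
    )
    img = 1.0 - spec.depth_contrast * centered.mask(x_um, y_um)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, shape)
    return ProjectedImage(img, pixel_size_um=pixel_um, modality="FIB")


class TestDetectRP:
    def test_noiseless_integer_center_recovered(self):
        spec = ReferencePatternSpec(center_um=(0, 0), arm_length_um=4.0, arm_width_um=0.6)
        img = _cross_image(spec, (120, 120), (60.0, 55.0), 0.1)
        det = detect_rp(img, spec, foreshortening=1.0)
        assert abs(det.center_px[0] - 60.0) < 0.1 and abs(det.center_px[1] - 55.0) < 0.1

    def test_translation_equivariant(self):
        spec = ReferencePatternSpec(center_um=(0, 0), arm_length_um=4.0, arm_width_um=0.6)
        img = _cross_image(spec, (120, 120), (60.0, 55.0), 0.1)
        det0 = detect_rp(img, spec, foreshortening=1.0)
        shifted = ProjectedImage(
            np.roll(img.data[0], (7, -9), axis=(0, 1)), pixel_size_um=0.1, modality="FIB"
        )
        det1 = detect_rp(shifted, spec, foreshortening=1.0)
        np.testing.assert_allclose(
            det1.center_px, (det0.center_px[0] - 9, det0.center_px[1] + 7), atol=1e-6
        )

    def test_image_without_cross_raises(self):
        rng = substream(0, "nocross")
        img = ProjectedImage(rng.normal(1.0, 0.05, (100, 100)), 0.1, "FIB")
        with pytest.raises(RPDetectionError, match="best match score"):
            detect_rp(img, ReferencePatternSpec(center_um=(0, 0)), foreshortening=1.0)

    def test_noisy_cross_rms_below_half_pixel(self):
        """SNR 10 Monte-Carlo smoke run (the full 100-trial version is part
        of the acceptance suite)."""
        spec = ReferencePatternSpec(center_um=(0, 0), arm_length_um=4.0, arm_width_um=0.6)
        errs = []
        for seed in range(15):
            rng = substream(seed, "rp-mc")
            c = (60 + rng.uniform(-0.5, 0.5), 55 + rng.uniform(-0.5, 0.5))
            img = _cross_image(spec, (120, 120), c, 0.1, noise_sigma=spec.depth_contrast / 10, rng=rng)
            det = detect_rp(img, spec, foreshortening=1.0)
            errs.append((det.center_px[0] - c[0]) ** 2 + (det.center_px[1] - c[1]) ** 2)
        assert np.sqrt(np.mean(errs)) < 0.5


class TestCalibrate:
    def test_pixel_size_arithmetic_from_fov(self):
        """84 um over 1536 px is the nominal 54 nm pixel of both modalities."""
        assert nominal_pixel_nm(84.0, 1536) == 54
        geom = MillingGeometry(fov_um=84.0, image_px=1536)
        assert int(geom.pixel_size_um * 1000) == 54

    def test_identical_images_give_unit_ratio(self):
        scene = random_scene(21, noise_sigma=0.0)
        geom = MillingGeometry(milling_angle_deg=18.0, fov_um=16.0, image_px=320)
        fib = render_fib_view(scene, geom)
        calib = calibrate(fib, fib, scene.rp)
        assert calib.scale_ratio == 1.0
        np.testing.assert_allclose(calib.rp_center_lm_px, calib.rp_center_fib_px)

    def test_half_sampling_ratio_recovered_from_arm_lengths(self):
        """Same scene at half the sampling: arm-length ratio resolves 2.0
        within 1%, so no cross-check warning fires even at 1% tolerance."""
        import warnings

        scene = random_scene(22, noise_sigma=0.0)
        fine = render_fib_view(scene, MillingGeometry(18.0, fov_um=13.0, image_px=520))
        coarse = render_fib_view(scene, MillingGeometry(18.0, fov_um=16.0, image_px=320))
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            calib = calibrate(coarse, fine, scene.rp, tolerance=0.01)
        assert calib.scale_ratio == pytest.approx(2.0)

    def test_metadata_mismatch_warns(self):
        scene = random_scene(23, noise_sigma=0.0)
        geom = MillingGeometry(milling_angle_deg=18.0, fov_um=16.0, image_px=320)
        fib = render_fib_view(scene, geom)
        lying = ProjectedImage(
            fib.data.copy(),
            pixel_size_um=fib.pixel_size_um * 1.1,
            modality="FIB",
            channels=fib.channels,
            provenance=dict(fib.provenance),
        )
        with pytest.warns(UserWarning, match="cross-check"):
            calibrate(lying, fib, scene.rp)


class TestOffsetsAndMapping:
    def _calib(self):
        return CalibrationResult(54.0, 54.0, (100.0, 100.0), (200.0, 150.0))

    def test_target_at_rp_center_is_zero(self):
        img = ProjectedImage(np.zeros((10, 10)), 0.054, "LM_via_FIB")
        dx, dy, d = measure_offset(img, (100.0, 100.0), (100.0, 100.0), self._calib())
        assert (dx, dy, d) == (0.0, 0.0, 0.0)

    def test_pixel_to_micron_arithmetic(self):
        """(100, -50) px at a 54 nm pixel is (5.4, -2.7) um."""
        img = ProjectedImage(np.zeros((10, 10)), 0.054, "LM_via_FIB")
        dx, dy, d = measure_offset(img, (200.0, 50.0), (100.0, 100.0), self._calib())
        np.testing.assert_allclose((dx, dy), (5.4, -2.7), rtol=1e-12)
        np.testing.assert_allclose(d, np.hypot(5.4, 2.7), rtol=1e-12)

    def test_zero_offset_maps_onto_rp_center(self):
        assert map_to_fib((0.0, 0.0), self._calib()) == (200.0, 150.0)

    def test_offset_maps_via_fib_pixel_size(self):
        calib = CalibrationResult(54.0, 27.0, (0.0, 0.0), (100.0, 100.0))
        fx, fy = map_to_fib((5.4, -2.7), calib)
        np.testing.assert_allclose((fx, fy), (300.0, 0.0))

    def test_mapping_outside_image_raises(self):
        with pytest.raises(ValueError, match="outside"):
            map_to_fib((100.0, 0.0), self._calib(), fib_shape_hw=(300, 300))

    def test_target_record_invariants(self):
        with pytest.raises(ValueError):
            TargetRecord((1.0, 2.0), (0.0, 0.0), sigma_loc_nm=-1.0)


class TestLocalizationPrecision:
    def test_worst_case_budget_four_pixels(self):
        """4 px at 54 nm/px is 216 nm — 'approximately 200 nm' at 1 s.f."""
        assert localization_precision(54.0, (2.0, 4.0)) == pytest.approx(216.0)

    def test_zero_error_gives_zero(self):
        assert localization_precision(54.0, 0.0) == 0.0

    def test_quadrature_of_two_picks(self):
        got = localization_precision(54.0, (2.0, 2.0), mode="quadrature")
        assert got == pytest.approx(54.0 * 2.0 * np.sqrt(2.0))

    @settings(deadline=None, max_examples=60)
    @given(
        px=st.floats(1.0, 200.0),
        errs=st.lists(st.floats(0.0, 10.0), min_size=1, max_size=4),
        bump=st.floats(0.0, 5.0),
        mode=st.sampled_from(["worst_case", "quadrature"]),
    )
    def test_monotone_in_pixel_and_error(self, px, errs, bump, mode):
        base = localization_precision(px, errs, mode)
        assert localization_precision(px * 1.5, errs, mode) >= base
        bigger = list(errs)
        bigger[0] += bump
        assert localization_precision(px, bigger, mode) >= base

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            localization_precision(54.0, -1.0)
        with pytest.raises(ValueError):
            localization_precision(54.0, 2.0, mode="rms")


class TestLocateSpot:
    def test_grid_centered_spot_recovered_exactly(self):
        rng = substream(1, "spot")
        img = gaussian_spot_image(rng, (41, 41), (20.0, 20.0))
        fit = locate_spot(img)
        np.testing.assert_allclose(fit.position_px, (20.0, 20.0), atol=1e-3)

    def test_subpixel_offset_rms_small(self):
        """0.3 px offsets at SNR 20: smoke run of the recovery statistics."""
        errs = []
        for seed in range(20):
            rng = substream(seed, "spot-mc")
            c = (20.3, 19.7)
            img = gaussian_spot_image(rng, (41, 41), c, noise_sigma=1 / 20)
            fit = locate_spot(img, approx_px=(20, 20))
            errs.append((fit.position_px[0] - c[0]) ** 2 + (fit.position_px[1] - c[1]) ** 2)
        assert np.sqrt(np.mean(errs)) < 0.1

    def test_flat_image_raises(self):
        with pytest.raises(SpotNotFoundError):
            locate_spot(np.ones((30, 30)))

    def test_3d_stack_spot_recovered(self):
        zz, yy, xx = np.mgrid[0:15, 0:21, 0:21].astype(float)
        c = (10.4, 9.6, 7.2)  # (x, y, z)
        vol = np.exp(
            -((xx - c[0]) ** 2 + (yy - c[1]) ** 2) / (2 * 1.5**2) - ((zz - c[2]) ** 2) / (2 * 2.0**2)
        )
        fit = locate_spot(vol, approx_px=(10, 10, 7))
        np.testing.assert_allclose(fit.position_px, c, atol=0.05)


class TestRegistrationPrinciple:
    @pytest.mark.parametrize("beta", [10.0, 18.0, 30.0])
    def test_rp_offset_mapping_hits_truth(self, beta):
        """One scene per angle here; the 21-scene sweep runs in acceptance."""
        from fibtarget import lm_via_fib, render_confocal
        from fibtarget.geometry import Frame3D

        scene = random_scene(31, noise_sigma=0.003)
        geom = MillingGeometry(milling_angle_deg=beta, fov_um=16.0, image_px=160)
        stack = render_confocal(scene, Frame3D((0.1, 0.1, 0.3)))
        proj = lm_via_fib(stack, geom)
        fib = render_fib_view(scene, geom)
        calib = calibrate(proj, fib, scene.rp)
        e = scene.emitters[0]
        truth3 = np.array(e.position_um)
        fit = locate_spot(
            proj.channel("green"), approx_px=tuple(proj.um_to_px(project_point(truth3, geom)))
        )
        dx, dy, _ = measure_offset(proj, fit.position_px, calib.rp_center_lm_px, calib)
        fx, fy = map_to_fib((dx, dy), calib, fib.shape_hw)
        truth_px = fib.um_to_px(project_point(truth3, geom))
        assert np.hypot(fx - truth_px[0], fy - truth_px[1]) < 1.0
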