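"""Limiting-aperture safety analysis and beam-profile metrics."""

import numpy as np
import pytest

from dcskit import (
    BeamProfile,
    allowed_power,
    beam_uniformity_report,
    fiber_to_camera_distance,
    fraction_in_aperture,
    generate_beam_image,
    iec_skin_cw_standard,
    max_aperture_averaged_irradiance,
    preprocess_frames,
    theoretical_snr_gain,
)

PITCH = 0.02  # mm


@pytest.fixture(scope="module")
def flat5():
    return generate_beam_image("flattop", diameter=5.0, pixel_pitch=PITCH)


@pytest.fixture(scope="module")
def gauss5():
    return generate_beam_image("gaussian", diameter=5.0, pixel_pitch=PITCH)


class TestFiberDistance:
    @pytest.mark.parametrize(
        "D, NA, expected", [(5.0, 0.22, 11.09), (5.0, 0.50, 4.330)]
    )
    def test_known_geometries(self, D, NA, expected):
        assert fiber_to_camera_distance(D, NA) == pytest.approx(expected, rel=1e-3)

    def test_small_na_diverges(self):
        assert fiber_to_camera_distance(5.0, 1e-6) > 1e6

    @pytest.mark.parametrize("na", [0.0, 1.0, 1.2])
    def test_invalid_na_rejected(self, na):
        with pytest.raises(ValueError):
            fiber_to_camera_distance(5.0, na)


class TestApertureScan:
    def test_large_flat_top_average_is_beam_irradiance(self, flat5):
        # aperture entirely inside the beam: average equals the flat level
        scan = max_aperture_averaged_irradiance(flat5, 3.5)
        beam_area_cm2 = np.pi * 0.25**2
        assert scan.irradiance == pytest.approx(
            flat5.total_power / beam_area_cm2, rel=0.01
        )

    def test_sub_aperture_beam_averaged_over_full_aperture(self):
        small = generate_beam_image("flattop", diameter=1.2, pixel_pitch=PITCH)
        scan = max_aperture_averaged_irradiance(small, 3.5)
        aperture_area_cm2 = np.pi * 0.175**2
        assert scan.irradiance == pytest.approx(
            small.total_power / aperture_area_cm2, rel=0.01
        )

    def test_gaussian_maximum_is_concentric(self, gauss5):
        scan = max_aperture_averaged_irradiance(gauss5, 3.5)
        cr, cc = gauss5.centroid_mm()
        assert scan.center_mm[0] == pytest.approx(cr, abs=2 * PITCH)
        assert scan.center_mm[1] == pytest.approx(cc, abs=2 * PITCH)

    def test_insufficient_margin_rejected(self):
        profile = BeamProfile(np.ones((50, 50)), pixel_pitch=PITCH)
        with pytest.raises(ValueError, match="margin"):
            max_aperture_averaged_irradiance(profile, 3.5)


class TestAllowedPower:
    def test_shape_only_dependence(self, gauss5):
        std = iec_skin_cw_standard()
        p1 = allowed_power(gauss5, std)
        p2 = allowed_power(gauss5.scaled_to_power(17.0), std)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_linear_in_mpe(self, flat5):
        std = iec_skin_cw_standard()
        double = type(std)(name="x2", mpe_irradiance=2 * std.mpe_irradiance)
        assert allowed_power(flat5, double) == pytest.approx(
            2 * allowed_power(flat5, std), rel=1e-12
        )

    def test_flat_top_is_optimal_for_same_support(self, flat5, gauss5):
        std = iec_skin_cw_standard()
        assert allowed_power(flat5, std) > allowed_power(gauss5, std)

    def test_zero_power_rejected(self):
        profile = BeamProfile(np.zeros((400, 400)), pixel_pitch=PITCH)
        with pytest.raises(ValueError):
            allowed_power(profile, iec_skin_cw_standard())


class TestFractionInAperture:
    def test_aperture_covering_support_is_unity(self, flat5):
        assert fraction_in_aperture(flat5, 20.0) == pytest.approx(1.0)

    def test_flat_top_geometric_ratio(self, flat5):
        assert fraction_in_aperture(flat5, 3.5) == pytest.approx(0.49, abs=0.005)

    def test_gaussian_closed_form(self, gauss5):
        # centred Gaussian, 1/e^2 radius w: fraction = 1 - exp(-2 r^2 / w^2)
        w, r = 2.5, 1.75
        expected = 1 - np.exp(-2 * r**2 / w**2)
        assert fraction_in_aperture(gauss5, 3.5) == pytest.approx(expected, rel=0.01)


class TestSnrGain:
    def test_identity(self):
        assert theoretical_snr_gain(1.0, 1.0, 1.0) == 1.0

    def test_reference_combination(self):
        assert theoretical_snr_gain(2.0, 0.8, 0.911) == pytest.approx(1.756, abs=1e-3)

    def test_linearity(self):
        base = theoretical_snr_gain(2.0, 0.8, 0.911)
        assert theoretical_snr_gain(4.0, 0.8, 0.911) == pytest.approx(2 * base)
        assert theoretical_snr_gain(2.0, 0.4, 0.911) == pytest.approx(base / 2)


class TestUniformityReport:
    def test_flat_top_radial_profile(self, flat5):
        report = beam_uniformity_report(flat5, smoothing_window=5)
        radii, mean = report["radial_profile"]
        inside = radii < 2.0
        outside = radii > 3.5
        level = mean[inside].mean()
        assert np.all(np.abs(mean[inside] - level) / level < 0.05)
        assert np.all(mean[outside & (radii < 4.0)] < 0.05 * level)

    def test_gaussian_radial_profile_matches_generator(self, gauss5):
        report = beam_uniformity_report(gauss5, smoothing_window=1)
        radii, mean = report["radial_profile"]
        keep = radii < 2.5
        expected = mean[0] * np.exp(-2 * radii[keep] ** 2 / 2.5**2)
        rms = np.sqrt(np.mean((mean[keep] - expected) ** 2)) / mean[0]
        assert rms < 0.02

    def test_gaussian_peak_exceeds_flat_top_at_equal_power(self, flat5, gauss5):
        rf = beam_uniformity_report(flat5, smoothing_window=5)
        rg = beam_uniformity_report(gauss5, smoothing_window=5)
        assert rg["peak_irradiance"] > rf["peak_irradiance"]


class TestPreprocessFrames:
    def test_identical_frames_zero_background(self):
        frame = np.random.default_rng(0).random((60, 60))
        profile = preprocess_frames([frame, frame], background=np.zeros((60, 60)))
        np.testing.assert_allclose(profile.irradiance, frame)

    def test_background_equal_to_mean_zeroes_profile(self):
        rng = np.random.default_rng(1)
        frames = [rng.random((40, 40)) for _ in range(5)]
        mean = np.mean(frames, axis=0)
        profile = preprocess_frames(frames, background=mean)
        np.testing.assert_allclose(profile.irradiance, 0.0, atol=1e-12)

    def test_noise_suppressed_by_averaging(self):
        rng = np.random.default_rng(2)
        n, sigma = 200, 1.0
        frames = [sigma * rng.standard_normal((50, 50)) for _ in range(n)]
        profile = preprocess_frames(frames, background=np.zeros((50, 50)))
        assert profile.irradiance.max() < 5 * sigma / np.sqrt(n)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            preprocess_frames([np.ones((4, 4)), np.ones((5, 5))])
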