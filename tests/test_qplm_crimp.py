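"""Orientation normalization and crimp morphometry."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ligaquant.qplm_crimp import (
    CrimpConfig,
    CrimpDetectionError,
    CrimpSegments,
    OrientationImage,
    ROI,
    crimp_angle,
    crimp_length,
    detect_crimp,
    extract_orientation_profile,
    mean_fiber_angle,
    normalize_orientation,
    sample_crimp_summary,
    select_rois,
)
from ligaquant.synth import PhantomSpecQPLM, generate_qplm_phantom


def _image(azimuth, retardance=None, axis_angle=0.0, pixel_size=1.0):
    return OrientationImage(
        azimuth=np.asarray(azimuth, float),
        retardance=retardance,
        pixel_size=pixel_size,
        longitudinal_axis_angle=axis_angle,
    )


class TestNormalizeOrientation:
    @pytest.mark.parametrize(
        "azimuth, expected",
        [(30.0, 0.0), (120.0, 90.0), (165.0, 45.0), (30.0 + 180.0, 0.0)],
    )
    def test_folding_relative_to_axis(self, azimuth, expected):
        img = _image([[azimuth]], axis_angle=30.0)
        assert normalize_orientation(img)[0, 0] == pytest.approx(expected)

    def test_range_is_0_to_90(self):
        rng = np.random.default_rng(0)
        img = _image(rng.uniform(-180, 180, (20, 20)), axis_angle=17.0)
        out = normalize_orientation(img)
        assert out.min() >= 0.0 and out.max() <= 90.0


class TestMeanFiberAngle:
    def test_parallel_fibers_mean_zero(self):
        img = _image(np.zeros((10, 10)))
        assert mean_fiber_angle(img) == 0.0

    def test_empty_mask_missing(self):
        img = _image(np.zeros((4, 4)))
        assert np.isnan(mean_fiber_angle(img, np.zeros((4, 4), bool)))

    def test_invariant_under_joint_rotation(self):
        """Rotating azimuths and the longitudinal axis together leaves
        the normalized mean unchanged."""
        rng = np.random.default_rng(1)
        azimuth = rng.uniform(0, 180, (16, 16))
        base = mean_fiber_angle(_image(azimuth, axis_angle=0.0))
        for rot in (13.0, 45.0, 90.0, 171.0):
            rotated = mean_fiber_angle(_image(azimuth + rot, axis_angle=rot))
            assert rotated == pytest.approx(base, abs=1e-9)

    def test_recovers_generator_truth_within_one_degree(self):
        spec = PhantomSpecQPLM(
            grid=(600, 600),
            crimp_angle_true=8.0,
            fiber_tilt=15.8,
            crimp_length_true=100.0,
            orientation_noise_sd=2.0,
            seed=5,
        )
        image, truth = generate_qplm_phantom(spec)
        assert mean_fiber_angle(image) == pytest.approx(
            truth.mean_fiber_angle_true, abs=1.0
        )


class TestSelectRois:
    def test_uniform_retardance_row_major_deterministic(self):
        img = _image(np.zeros((100, 100)), retardance=np.ones((100, 100)))
        rois = select_rois(img, n=2, size=(50, 50))
        assert [(r.row, r.col) for r in rois] == [(0, 0), (0, 50)]

    def test_rois_pairwise_disjoint(self):
        rng = np.random.default_rng(2)
        img = _image(
            np.zeros((200, 200)), retardance=rng.uniform(0.6, 1.0, (200, 200))
        )
        rois = select_rois(img, n=5, size=(40, 80))
        for i, a in enumerate(rois):
            for b in rois[i + 1 :]:
                assert not a.overlaps(b)

    def test_avoids_out_of_plane_region(self):
        spec = PhantomSpecQPLM(
            grid=(500, 520), out_of_plane_fraction=0.3, orientation_noise_sd=0.0
        )
        image, truth = generate_qplm_phantom(spec)
        rois = select_rois(image, n=5, size=(50, 500))
        for roi in rois:
            center_row = roi.row + roi.height // 2
            assert not truth.out_of_plane_mask[center_row, 0]

    def test_small_image_warns_and_returns_fewer(self):
        img = _image(np.zeros((60, 60)), retardance=np.ones((60, 60)))
        with pytest.warns(UserWarning):
            rois = select_rois(img, n=5, size=(50, 50))
        assert len(rois) == 1

    def test_no_retardance_all_in_plane(self):
        img = _image(np.zeros((100, 100)))
        rois = select_rois(img, n=2, size=(50, 50))
        assert all(r.in_plane for r in rois)


class TestOrientationProfile:
    def test_square_wave_profile(self, ideal_qplm):
        image, truth = ideal_qplm
        roi = ROI(0, 0, 50, 500)
        profile = extract_orientation_profile(image, roi, smooth_window=1)
        assert set(np.unique(profile)) == {-10.0, 10.0}

    def test_profile_length_equals_roi_width(self, ideal_qplm):
        image, _ = ideal_qplm
        profile = extract_orientation_profile(image, ROI(0, 0, 50, 321))
        assert profile.size == 321

    def test_transverse_averaging_reduces_noise_by_sqrt_height(self):
        rng = np.random.default_rng(3)
        h = 64
        noise = rng.normal(0, 2.0, (h, 400))
        img = _image(noise)
        wide = extract_orientation_profile(img, ROI(0, 0, h, 400), smooth_window=1)
        single = extract_orientation_profile(img, ROI(0, 0, 1, 400), smooth_window=1)
        ratio = np.std(single) / np.std(wide)
        assert ratio == pytest.approx(np.sqrt(h), rel=0.25)

    def test_roi_outside_image_rejected(self, ideal_qplm):
        image, _ = ideal_qplm
        with pytest.raises(ValueError):
            extract_orientation_profile(image, ROI(0, 300, 50, 500))


class TestDetectCrimp:
    def test_ideal_square_profile(self):
        x = np.arange(500)
        profile = np.where((x // 50) % 2 == 0, 10.0, -10.0)
        seg = detect_crimp(profile, pixel_size=1.0, edge_margin=0)
        assert seg.phi_upwards == pytest.approx(10.0)
        assert seg.phi_downwards == pytest.approx(10.0)
        assert np.allclose(np.diff(seg.valleys_um), 100.0)

    def test_single_sign_profile_rejected(self):
        with pytest.raises(CrimpDetectionError):
            detect_crimp(np.full(200, 5.0) + np.linspace(0, 1, 200), 1.0)

    def test_noisy_phantom_recovery_within_5_percent(self):
        spec = PhantomSpecQPLM(
            crimp_angle_true=18.8,
            crimp_length_true=150.0,
            orientation_noise_sd=2.0,
            seed=8,
        )
        image, _ = generate_qplm_phantom(spec)
        profile = extract_orientation_profile(image, ROI(0, 0, 50, 500))
        seg = detect_crimp(profile, image.pixel_size)
        assert seg.phi_upwards == pytest.approx(18.8, rel=0.05)
        assert seg.phi_downwards == pytest.approx(18.8, rel=0.05)
        assert np.diff(seg.valleys_um).mean() == pytest.approx(150.0, rel=0.05)


class TestCrimpAngleFormula:
    @pytest.mark.parametrize(
        "up, down, expected", [(10, 10, 10), (20, 30, 25), (0, 0, 0)]
    )
    def test_half_sum(self, up, down, expected):
        assert crimp_angle(up, down) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            crimp_angle(-1.0, 5.0)

    @given(
        up=st.floats(0, 89, allow_nan=False),
        down=st.floats(0, 89, allow_nan=False),
    )
    def test_symmetric_and_bounded(self, up, down):
        theta = crimp_angle(up, down)
        assert theta == crimp_angle(down, up)
        assert min(up, down) <= theta <= max(up, down)


class TestCrimpLength:
    def test_equal_spacing(self):
        seg = CrimpSegments(10, 10, np.array([0.0, 100.0, 200.0]), [])
        assert crimp_length(seg) == 100.0

    def test_mean_of_unequal_spacings(self):
        seg = CrimpSegments(10, 10, np.array([0.0, 90.0, 210.0]), [])
        assert crimp_length(seg) == 105.0

    def test_fewer_than_two_valleys_missing(self):
        seg = CrimpSegments(10, 10, np.array([50.0]), [])
        assert np.isnan(crimp_length(seg))


class TestSampleSummary:
    def test_ideal_phantom_summary_matches_single_roi(self, ideal_qplm):
        image, truth = ideal_qplm
        m = sample_crimp_summary(image)
        roi0 = m.per_roi[0]
        assert m.theta == pytest.approx(roi0["theta"])
        assert m.theta == pytest.approx(truth.crimp_angle_true, abs=0.5)
        assert m.n_rois >= 1

    def test_out_of_plane_rois_excluded_from_average(self):
        spec = PhantomSpecQPLM(
            grid=(250, 520),
            out_of_plane_fraction=0.2,
            orientation_noise_sd=0.0,
        )
        image, _ = generate_qplm_phantom(spec)
        m = sample_crimp_summary(image, CrimpConfig(n_rois=5))
        assert 0 < m.n_rois < 5

    def test_fully_out_of_plane_sample_flagged_excluded(self):
        spec = PhantomSpecQPLM(grid=(250, 520), out_of_plane_fraction=1.0)
        image, _ = generate_qplm_phantom(spec)
        m = sample_crimp_summary(image)
        assert m.excluded and m.n_rois == 0 and np.isnan(m.theta)

    def test_full_recovery_on_noisy_phantom(self):
        spec = PhantomSpecQPLM(
            crimp_angle_true=22.2,
            crimp_length_true=100.0,
            orientation_noise_sd=2.0,
            seed=21,
        )
        image, _ = generate_qplm_phantom(spec)
        m = sample_crimp_summary(image)
        assert m.theta == pytest.approx(22.2, rel=0.05)
        assert m.crimp_length == pytest.approx(100.0, rel=0.05)


class TestGeometryInvariants:
    @pytest.mark.parametrize("theta_true", [5.0, 15.0, 25.0])
    @pytest.mark.parametrize("length_true", [50.0, 100.0, 200.0])
    def test_noiseless_exact_recovery_grid(self, theta_true, length_true):
        """Noiseless triangular phantoms: theta within 0.5 degrees and
        length within one pixel across the design grid."""
        spec = PhantomSpecQPLM(
            grid=(100, 640),
            crimp_angle_true=theta_true,
            crimp_length_true=length_true,
            orientation_noise_sd=0.0,
            seed=0,
        )
        image, _ = generate_qplm_phantom(spec)
        m = sample_crimp_summary(image, CrimpConfig(n_rois=1, roi_width=620))
        assert m.theta == pytest.approx(theta_true, abs=0.5)
        assert m.crimp_length == pytest.approx(length_true, abs=image.pixel_size)

    def test_length_scales_with_pixel_size(self):
        base = PhantomSpecQPLM(
            grid=(60, 520),
            crimp_length_true=100.0,
            orientation_noise_sd=0.0,
            pixel_size=1.0,
        )
        img1, _ = generate_qplm_phantom(base)
        img2 = OrientationImage(
            azimuth=img1.azimuth.copy(),
            retardance=None,
            pixel_size=2.0,
            longitudinal_axis_angle=0.0,
        )
        m1 = sample_crimp_summary(img1, CrimpConfig(n_rois=1))
        m2 = sample_crimp_summary(img2, CrimpConfig(n_rois=1))
        assert m2.crimp_length == pytest.approx(2 * m1.crimp_length, rel=1e-9)

    @pytest.mark.parametrize("tilt", [0.0, 4.0, 10.0])
    def test_constant_tilt_absorbed(self, tilt):
        """A uniform fiber tilt up to 10 degrees does not move the
        crimp estimates (the profile is mean-centred)."""
        spec = PhantomSpecQPLM(
            grid=(80, 640),
            crimp_angle_true=15.0,
            crimp_length_true=80.0,
            fiber_tilt=tilt,
            orientation_noise_sd=0.0,
        )
        image, _ = generate_qplm_phantom(spec)
        m = sample_crimp_summary(image, CrimpConfig(n_rois=1, roi_width=620))
        assert m.theta == pytest.approx(15.0, abs=0.5)
        assert m.crimp_length == pytest.approx(80.0, abs=1.0)
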