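"""Feature tracking: line cuts, feature images, matching, trajectories."""

import numpy as np
import pytest

from lvtrack import phantom
from lvtrack.imageio import ImageSeries
from lvtrack.segmentation import BorderContour, segment_series
from lvtrack.tracking import (BoundaryTrajectories, LineCutSet,
                              build_feature_image, interpolate_line_cuts,
                              match_features, track_series,
                              trajectories_to_velocity, _match_all,
                              _feature_matrix)


def circle_contour(frame_index=0, center=(31.5, 31.5), radius=14.0,
                   n_points=32):
    ang = np.arange(n_points) * 2 * np.pi / n_points
    pts = np.stack([center[0] + radius * np.sin(ang),
                    center[1] + radius * np.cos(ang)], axis=1)
    c = BorderContour.from_points(frame_index, pts)
    c.frame_index = frame_index
    return c


def synthetic_cuts(rng, n=32, length=9, frame_index=0):
    profiles = rng.normal(size=(n, length))
    return LineCutSet(frame_index, profiles, np.full(n, 14.0),
                      np.arange(n) * 2 * np.pi / n,
                      np.zeros((n, length), bool), 1.0, (31.5, 31.5))


class TestLineCuts:
    def test_radial_ramp_profiles(self):
        """Analytic field oracle: on I = r the profiles are linear ramps of
        slope = step size."""
        rows, cols = np.mgrid[0:64, 0:64]
        frame = np.hypot(rows - 31.5, cols - 31.5)
        contour = circle_contour()
        cuts = interpolate_line_cuts(frame, contour, cut_len=9, cut_step=1.0)
        expected = 14.0 + np.arange(-4, 5) * 1.0
        assert np.allclose(cuts.profiles, expected[None, :], atol=0.05)

    def test_constant_frame_constant_profiles(self):
        cuts = interpolate_line_cuts(np.full((64, 64), 7.0),
                                     circle_contour(), 9, 1.0)
        assert np.allclose(cuts.profiles, 7.0)

    def test_step_edge_gradient_at_centre(self):
        frame = np.where(np.hypot(*[g - 31.5 for g in np.mgrid[0:64, 0:64]])
                         <= 14.0, 1000.0, 100.0)
        cuts = interpolate_line_cuts(frame, circle_contour(), 9, 1.0)
        grad = np.abs(np.diff(cuts.profiles, axis=1))
        centre = (cuts.profiles.shape[1] - 1) // 2
        peak = np.argmax(grad, axis=1) + 0.5
        assert np.all(np.abs(peak - centre) <= 1.0)

    def test_even_length_rejected(self):
        with pytest.raises(ValueError):
            interpolate_line_cuts(np.zeros((8, 8)), circle_contour(), 8, 1.0)


class TestFeatureImages:
    def test_window_one_is_single_profile(self, rng):
        cuts = synthetic_cuts(rng)
        fi = build_feature_image(cuts, 5, window=1)
        assert np.array_equal(fi.patch[0], cuts.profiles[5])

    def test_cyclic_window_indices(self, rng):
        cuts = synthetic_cuts(rng)
        fi = build_feature_image(cuts, 0, window=7)
        expected = cuts.profiles[[29, 30, 31, 0, 1, 2, 3]]
        assert np.array_equal(fi.patch, expected)

    def test_even_window_rejected(self, rng):
        with pytest.raises(ValueError):
            build_feature_image(synthetic_cuts(rng), 0, window=4)

    def test_shifted_texture_gives_shifted_feature_images(self, rng):
        cuts1 = synthetic_cuts(rng)
        cuts2 = LineCutSet(1, np.roll(cuts1.profiles, 2, axis=0),
                           cuts1.radii_px, cuts1.angles, cuts1.oob,
                           1.0, cuts1.centroid)
        fi1 = build_feature_image(cuts1, 4, window=5)
        fi2 = build_feature_image(cuts2, 6, window=5)
        assert np.allclose(fi1.patch, fi2.patch)


class TestMatching:
    def test_identical_frames_match_self(self, rng):
        cuts = synthetic_cuts(rng)
        fi = build_feature_image(cuts, 7, window=5)
        idx, score, low = match_features(fi, cuts, search_half_width=4)
        assert idx == 7
        assert score == pytest.approx(1.0)
        assert not low

    def test_circular_shift_recovered_exactly(self, rng):
        cuts1 = synthetic_cuts(rng)
        shifted = LineCutSet(1, np.roll(cuts1.profiles, 2, axis=0),
                             cuts1.radii_px, cuts1.angles, cuts1.oob,
                             1.0, cuts1.centroid)
        for i in (0, 5, 30):
            fi = build_feature_image(cuts1, i, window=5)
            idx, score, low = match_features(fi, shifted,
                                             search_half_width=4)
            assert idx == (i + 2) % cuts1.n_cuts
            assert score == pytest.approx(1.0)

    def test_featureless_frames_flagged(self):
        n = 16
        cuts = LineCutSet(0, np.zeros((n, 9)), np.full(n, 10.0),
                          np.arange(n) * 2 * np.pi / n,
                          np.zeros((n, 9), bool), 1.0, (0.0, 0.0))
        fi = build_feature_image(cuts, 3, window=3)
        idx, score, low = match_features(fi, cuts, search_half_width=3)
        assert idx == 3          # zero displacement
        assert low

    def test_shift_equivariance_all_points(self, rng):
        """Circularly shifting the texture by k cuts shifts every match by
        exactly k."""
        cuts1 = synthetic_cuts(rng, n=24)
        for k in (1, 3, 5):
            shifted = LineCutSet(1, np.roll(cuts1.profiles, k, axis=0),
                                 cuts1.radii_px, cuts1.angles, cuts1.oob,
                                 1.0, cuts1.centroid)
            f1 = _feature_matrix(cuts1, 5)
            f2 = _feature_matrix(shifted, 5)
            disp, score, low = _match_all(f1, f2, search_half_width=6,
                                          min_score=0.3)
            assert np.allclose(disp, k, atol=1e-6)
            assert np.allclose(score, 1.0)

    def test_windowed_search_matches_brute_force(self, rng):
        """On a small contour, exhaustive matching equals the windowed
        search whenever the true displacement is inside the window."""
        cuts1 = synthetic_cuts(rng, n=16)
        for k in (-3, 0, 2):
            shifted = LineCutSet(1, np.roll(cuts1.profiles, k, axis=0),
                                 cuts1.radii_px, cuts1.angles, cuts1.oob,
                                 1.0, cuts1.centroid)
            f1 = _feature_matrix(cuts1, 3)
            f2 = _feature_matrix(shifted, 3)
            windowed, _, _ = _match_all(f1, f2, search_half_width=4,
                                        min_score=0.3, refine=False)
            brute, _, _ = _match_all(f1, f2, search_half_width=8,
                                     min_score=0.3, refine=False)
            assert np.array_equal(windowed % 16, brute % 16)


class TestTrajectories:
    def test_static_series_constant(self, static_series):
        import copy

        first, _ = segment_series(static_series)
        contours = []
        for t in range(static_series.n_frames):
            c = copy.deepcopy(first[0])
            c.frame_index = t
            contours.append(c)
        traj = track_series(static_series, contours)
        assert np.allclose(traj.radius_px, traj.radius_px[0], atol=1e-9)
        assert np.allclose(traj.angle_rad, traj.angle_rad[0], atol=1e-9)

    def test_rigid_rotation_recovered(self):
        """Applied-transform oracle: 0.05 rad/frame rigid rotation."""
        ser, rate = _rotating_series(0.05)
        contours, _ = segment_series(ser)
        traj = track_series(ser, contours)
        step = np.diff(traj.mean_angle())
        assert abs(step.mean() - rate) < 0.1 * rate

    def test_pure_contraction_no_spurious_rotation(self):
        ser, per_frame_px = _contracting_series(-0.5)
        contours, _ = segment_series(ser)
        traj = track_series(ser, contours)
        dr = np.diff(traj.radius_px.mean(axis=1))
        assert abs(dr.mean() - per_frame_px) < 0.1 * abs(per_frame_px)
        dang = np.diff(traj.mean_angle())
        assert np.abs(dang).mean() < 0.005

    def test_velocity_arithmetic(self):
        times = np.array([0.0, 20.0])
        radius = np.array([[10.0, 10.0], [10.5, 10.5]])   # px at 2 mm/px
        angle = np.tile(np.array([0.0, np.pi]), (2, 1))
        traj = BoundaryTrajectories(radius, angle, np.ones((1, 2)), times)
        traces = trajectories_to_velocity(traj, spacing=2.0,
                                          smooth_window=None)
        # 0.5 px * 2 mm/px = 1 mm over 20 ms -> 50 mm/s
        assert traces.v_rad[0] == pytest.approx(50.0)
        assert traces.v_circ[0] == pytest.approx(0.0)
        assert traces.times_ms[0] == pytest.approx(10.0)

    def test_zero_displacement_zero_velocity(self):
        times = np.arange(4) * 20.0
        radius = np.full((4, 8), 12.0)
        angle = np.tile(np.arange(8) * np.pi / 4, (4, 1))
        traj = BoundaryTrajectories(radius, angle, np.ones((3, 8)), times)
        traces = trajectories_to_velocity(traj, 1.8, smooth_window=None)
        assert np.allclose(traces.v_rad, 0.0)
        assert np.allclose(traces.v_circ, 0.0)

    def test_nonincreasing_times_rejected(self):
        traj = BoundaryTrajectories(np.ones((2, 4)), np.ones((2, 4)),
                                    np.ones((1, 4)), np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            trajectories_to_velocity(traj, 1.8)

    def test_no_angular_drift_over_cycles(self, small_subject):
        """Periodic motion accumulates no net rotation: the tracked mean
        angle returns to its start at each end-diastole (drift per cycle
        below 0.02 rad, noiseless)."""
        ser = small_subject.series[0]
        contours, _ = segment_series(ser)
        traj = track_series(ser, contours)
        m = traj.mean_angle()
        bidx = np.searchsorted(ser.frame_times,
                               small_subject.schedule.start_times)
        bidx = bidx[bidx < len(m)]
        n_cycles = len(bidx) - 1
        assert n_cycles >= 2
        drift = abs(m[bidx[-1]] - m[bidx[0]]) / n_cycles
        assert drift <= 0.02

    def test_breathing_translation_removed_by_centroid(self):
        """A slow whole-frame translation (free-breathing surrogate) does
        not corrupt velocities measured about the per-frame centroid."""
        p = phantom.MotionParams(theta_amp=-0.15)
        subj = phantom.generate_subject(
            [p, p], n_cycles=2, seed=6,
            settings=phantom.RenderSettings(noise_sd=0.0),
            breathing_amp_mm=3.0)
        ser = subj.series[0]
        gt = subj.truth[0]
        contours, _ = segment_series(ser)
        # the centroid really moves with breathing
        cents = np.array([c.centroid for c in contours])
        assert np.ptp(cents[:, 0]) * ser.pixel_spacing > 2.0
        traj = track_series(ser, contours)
        traces = trajectories_to_velocity(traj, ser.pixel_spacing)
        rms_r = np.sqrt(np.mean((traces.v_rad - gt.v_rad) ** 2))
        assert rms_r <= 0.15 * np.abs(gt.v_rad).max()

    def test_basal_slice_in_phase(self, small_subject):
        """Systolic radial and circumferential velocity carry the same sign
        in a basal (clockwise) slice: twisting accompanies contraction."""
        ser = small_subject.series[0]      # theta_amp < 0
        contours, _ = segment_series(ser)
        traj = track_series(ser, contours)
        traces = trajectories_to_velocity(traj, ser.pixel_spacing)
        gt = small_subject.truth[0]
        systole = gt.v_rad < -0.3 * np.abs(gt.v_rad).max()
        frac_same_sign = np.mean(
            np.sign(traces.v_circ[systole]) == np.sign(traces.v_rad[systole]))
        assert frac_same_sign > 0.9


def _rotating_series(rate, n_frames=40):
    p = phantom.MotionParams(r_ed=25.0, r_es=15.0, theta_amp=0.15)
    settings = phantom.RenderSettings(noise_sd=0.0)
    ren = phantom._SliceRenderer(p, settings,
                                 phantom._texture_field(
                                     np.random.default_rng(8)))
    frames = np.stack([ren.render(22.0, rate * t, None)
                       for t in range(n_frames)])
    return ImageSeries(frames, np.arange(n_frames) * 20.0,
                       settings.pixel_spacing), rate


def _contracting_series(px_per_frame, n_frames=20):
    p = phantom.MotionParams(r_ed=25.0, r_es=15.0, theta_amp=0.15)
    settings = phantom.RenderSettings(noise_sd=0.0)
    ren = phantom._SliceRenderer(p, settings,
                                 phantom._texture_field(
                                     np.random.default_rng(8)))
    radii = 25.0 + px_per_frame * settings.pixel_spacing * np.arange(n_frames)
    frames = np.stack([ren.render(r, 0.0, None) for r in radii])
    return ImageSeries(frames, np.arange(n_frames) * 20.0,
                       settings.pixel_spacing), px_per_frame
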