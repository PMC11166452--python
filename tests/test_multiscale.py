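import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tortuosity as tt
from tortuosity.multiscale import angle_profile, lambda_grid


class TestIncrementAndAngle:
    def test_straight_increment_norm(self, straight_track):
        v = tt.increment(straight_track, 0, 25)  # lambda = 1.0 m
        assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-9)

    def test_full_length_increment_is_net_displacement(self, straight_track):
        n = straight_track.n_points
        v = tt.increment(straight_track, 0, n - 1)
        np.testing.assert_allclose(
            v, straight_track.points[-1] - straight_track.points[0])

    def test_out_of_range(self, straight_track):
        with pytest.raises(IndexError):
            tt.increment(straight_track, 300, 100)

    def test_straight_angle_zero(self, straight_track):
        assert tt.curvature_angle(straight_track, 10, 25) == pytest.approx(0.0, abs=1e-7)

    def test_right_angle_corner(self):
        pts = np.array([[0, 0], [1, 0], [1, 1]], float)
        track = tt.resample_uniform(pts, ds=0.5)
        assert tt.curvature_angle(track, 0, 2) == pytest.approx(90.0)

    def test_circle_closed_form(self):
        # equal chords of a constant-curvature track turn by the arc angle:
        # R = 4.7746 m, lambda = 1 m -> theta = (180/pi)/4.7746 = 12.0003 deg
        R = 4.7746
        track = tt.gen_circle(R, 12.80, ds=0.04)
        theta = tt.curvature_angle(track, 0, 25)
        assert theta == pytest.approx(np.degrees(1.0 / R), abs=1e-9)

    def test_zero_norm_increment_raises(self):
        pts = np.array([[0, 0], [1, 0], [0, 0], [1, 0], [0, 0]], float)
        track = tt.ArclengthTrack(pts, ds=1.0)
        with pytest.raises(ZeroDivisionError):
            tt.curvature_angle(track, 0, 2)  # X(s+2lam)=X(s): zero increment


class TestAngleProfile:
    @pytest.mark.parametrize("lam,expected", [(0.04, 319), (6.40, 1), (3.20, 161)])
    def test_sample_counts_on_12p8m_track(self, straight_track, lam, expected):
        assert len(angle_profile(straight_track, lam)) == expected

    def test_too_long_scale_empty(self, straight_track):
        prof = angle_profile(straight_track, 6.44)
        assert prof.empty

    def test_count_formula_matches_enumeration(self):
        # exhaustive index enumeration vs floor((L - 2 lam)/ds) + 1
        ds = 0.04
        for n_steps in [10, 41, 160, 321]:
            track = tt.gen_line(n_steps * ds, ds=ds)
            for k in [1, 2, 5, n_steps // 2, n_steps]:
                brute = sum(1 for i in range(track.n_points)
                            if i + 2 * k <= track.n_points - 1)
                prof = angle_profile(track, k * ds)
                assert len(prof) == brute
                L = track.total_arclength
                formula = max(0, int(np.floor((L - 2 * k * ds) / ds + 1e-9)) + 1)
                assert len(prof) == formula

    def test_dist_goal_at_shared_vertex(self):
        track = tt.gen_line(2.0, ds=0.5)  # along +x from origin
        prof = angle_profile(track, 0.5, goal=(0.0, 0.0))
        # shared vertex of sample starting at s is X(s + lam)
        np.testing.assert_allclose(prof["dist_goal"], [0.5, 1.0, 1.5])

    def test_non_multiple_scale_rejected(self, straight_track):
        with pytest.raises(ValueError):
            angle_profile(straight_track, 0.05)


class TestScaleCurves:
    def test_default_grid_has_160_scales(self):
        assert len(lambda_grid()) == 160

    def test_mean_curve_on_straight_line(self, straight_track):
        curve = tt.mean_angle_curve(straight_track)
        assert len(curve.lam) == 160
        np.testing.assert_allclose(curve.mean_theta, 0.0, atol=1e-6)
        assert curve.n_samples[0] == 319 and curve.n_samples[-1] == 1

    def test_mean_curve_on_circle(self):
        R = 4.7746
        track = tt.gen_circle(R, 12.80, ds=0.04)
        curve = tt.mean_angle_curve(track)
        expected = tt.circle_theta(R, curve.lam)
        np.testing.assert_allclose(curve.mean_theta, expected, atol=1e-6)

    def test_grand_mean_basics(self, straight_track):
        c1 = tt.mean_angle_curve(straight_track)
        gm = tt.grand_mean_curve([c1, c1])
        np.testing.assert_allclose(gm.mean_theta, c1.mean_theta, atol=1e-12)
        assert np.all(gm.n_samples == 2)

    def test_grand_mean_averages_and_handles_missing(self):
        lam = np.array([0.5, 1.0])
        a = tt.ScaleCurve(lam, [0.0, 10.0], [5, 5])
        b = tt.ScaleCurve(lam, [90.0, np.nan], [5, 0])
        gm = tt.grand_mean_curve([a, b])
        np.testing.assert_allclose(gm.mean_theta, [45.0, 10.0])
        np.testing.assert_array_equal(gm.n_samples, [2, 1])

    def test_grand_mean_grid_mismatch(self):
        a = tt.ScaleCurve([0.5], [1.0], [1])
        b = tt.ScaleCurve([0.6], [1.0], [1])
        with pytest.raises(ValueError):
            tt.grand_mean_curve([a, b])
        with pytest.raises(ValueError):
            tt.grand_mean_curve([])


class TestSlopeFits:
    def test_circle_loglog_slope_unity(self):
        curve = tt.mean_angle_curve(tt.gen_circle(20.0, 12.80))
        fit = tt.fit_slope(curve, (0.04, 1.0), space="log-log")
        assert fit.slope == pytest.approx(1.0, abs=1e-3)

    def test_spiral_rate_12_deg_per_m(self):
        # one full turn per 30 m of path: R = 30 / (2 pi)
        R = 30.0 / (2 * np.pi)
        curve = tt.mean_angle_curve(tt.gen_circle(R, 12.80))
        fit = tt.fit_slope(curve, (1.2, 6.4), space="lin-lin")
        assert fit.slope == pytest.approx(12.0, abs=0.1)

    def test_constant_curve_zero_slope(self):
        lam = lambda_grid(0.04, 2.0)
        curve = tt.ScaleCurve(lam, np.full(len(lam), 33.0), np.full(len(lam), 9))
        fit = tt.fit_slope(curve, (0.04, 2.0), space="lin-lin")
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(33.0)

    def test_insufficient_points(self):
        curve = tt.ScaleCurve([0.5, 1.0], [1.0, 2.0], [1, 1])
        with pytest.raises(ValueError):
            tt.fit_slope(curve, (0.4, 1.1), space="lin-lin")

    def test_nonpositive_theta_dropped_with_warning(self):
        lam = lambda_grid(0.04, 0.4)
        theta = np.linspace(0.0, 5.0, len(lam))  # first entry exactly 0
        curve = tt.ScaleCurve(lam, theta, np.full(len(lam), 3))
        with pytest.warns(RuntimeWarning):
            fit = tt.fit_slope(curve, (0.04, 0.4), space="log-log")
        assert fit.n_points == len(lam) - 1


class TestInvariances:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(angle=st.floats(-np.pi, np.pi), tx=st.floats(-5, 5), ty=st.floats(-5, 5),
           reflect=st.booleans())
    def test_theta_rigid_motion_invariant(self, angle, tx, ty, reflect):
        track = tt.gen_wormlike(5.0, 4.0, seed=42)
        base = tt.mean_angle_curve(track, lambda_grid(0.04, 1.0))
        R = np.array([[np.cos(angle), -np.sin(angle)],
                      [np.sin(angle), np.cos(angle)]])
        pts = track.points @ R.T + [tx, ty]
        if reflect:
            pts = pts * [1.0, -1.0]
        moved = tt.ArclengthTrack(pts, track.ds)
        curve = tt.mean_angle_curve(moved, lambda_grid(0.04, 1.0))
        np.testing.assert_allclose(curve.mean_theta, base.mean_theta, atol=1e-8)

    def test_theta_scale_invariant(self):
        track = tt.gen_wormlike(5.0, 4.0, seed=43)
        c = 3.0
        scaled = tt.ArclengthTrack(track.points * c, track.ds * c)
        base = tt.mean_angle_curve(track, lambda_grid(0.04, 1.0))
        curve = tt.mean_angle_curve(scaled, c * lambda_grid(0.04, 1.0))
        np.testing.assert_allclose(curve.mean_theta, base.mean_theta, atol=1e-8)
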