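import math

import numpy as np
import pytest

import tortuosity as tt
from tortuosity.segmentation import wrap_angle


class TestDeterminismAndSpacing:
    @pytest.mark.parametrize("maker", [
        lambda s: tt.gen_wormlike(10.0, 6.0, seed=s),
        lambda s: tt.gen_uncorrelated(0.04, 6.0, seed=s),
        lambda s: tt.gen_search(seed=s),
        lambda s: tt.gen_approach((10.0, 0.0), (0.0, 0.0), seed=s),
    ])
    def test_same_seed_identical_different_seed_not(self, maker):
        a, b, c = maker(1), maker(1), maker(2)
        np.testing.assert_array_equal(a.points, b.points)
        assert a.points.shape != c.points.shape or not np.allclose(a.points, c.points)

    @pytest.mark.parametrize("track", [
        tt.gen_line(5.0), tt.gen_circle(3.0, 5.0),
        tt.gen_wormlike(10.0, 5.0, seed=0), tt.gen_uncorrelated(0.2, 5.0, seed=0),
        tt.gen_search(seed=0), tt.gen_approach((5.0, 0.0), (0.0, 0.0), seed=0),
    ])
    def test_exact_grid_spacing(self, track):
        track.validate_spacing()


class TestLineAndCircle:
    def test_line_point_count_and_angles(self):
        track = tt.gen_line(12.80, ds=0.04)
        assert track.n_points == 321
        curve = tt.mean_angle_curve(track, tt.lambda_grid(0.04, 2.0))
        np.testing.assert_allclose(curve.mean_theta, 0.0, atol=1e-6)

    def test_line_heading(self):
        h = tt.headings(tt.gen_line(5.0, heading=90.0), 0.04)
        np.testing.assert_allclose(h, 90.0)

    def test_circle_one_turn_per_30m(self):
        # R = 30 / (2 pi) gives a turning rate of 360 deg per 30 m of path
        R = 30.0 / (2 * math.pi)
        track = tt.gen_circle(R, 30.0)
        h = np.degrees(np.arctan2(*np.diff(track.points, axis=0).T[::-1]))
        turns = np.abs(wrap_angle(np.diff(h)))
        rate = turns.sum() / (len(turns) * track.ds)
        assert rate == pytest.approx(360.0 / 30.0, rel=1e-9)

    def test_circle_theta_linear_in_lambda(self):
        track = tt.gen_circle(5.0, 12.8)
        curve = tt.mean_angle_curve(track, tt.lambda_grid(0.04, 2.0))
        ratio = curve.mean_theta / curve.lam
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)


class TestWormlike:
    def test_heading_increment_variance(self):
        # sample variance of heading increments ~ ds / persistence
        persistence, ds = 8.0, 0.04
        track = tt.gen_wormlike(persistence, 4000.0, ds=ds, seed=5)
        v = np.diff(track.points, axis=0)
        psi = np.unwrap(np.arctan2(v[:, 1], v[:, 0]))
        var = np.var(np.diff(psi))
        assert var == pytest.approx(ds / persistence, rel=0.05)

    def test_brownian_loglog_slope(self):
        curves = [tt.mean_angle_curve(tt.gen_wormlike(10.0, 12.8, seed=s),
                                      tt.lambda_grid(0.04, 1.0))
                  for s in range(50)]
        fit = tt.fit_slope(tt.grand_mean_curve(curves), (0.04, 1.0), "log-log")
        assert fit.slope == pytest.approx(0.5, abs=0.1)

    def test_infinite_persistence_degenerates_to_line(self):
        track = tt.gen_wormlike(math.inf, 5.0, seed=6)
        np.testing.assert_allclose(track.points, tt.gen_line(5.0).points, atol=1e-9)


class TestUncorrelated:
    def test_grand_mean_90_deg_at_large_scales(self):
        grid = tt.lambda_grid(1.0, 6.4, 0.2)  # lambda >= 25 steps of 0.04
        curves = [tt.mean_angle_curve(tt.gen_uncorrelated(0.04, 12.8, seed=s), grid)
                  for s in range(100)]
        gm = tt.grand_mean_curve(curves)
        assert np.nanmean(gm.mean_theta) == pytest.approx(90.0, abs=2.0)

    def test_net_displacement_diffusive_scaling(self):
        # E[R^2] = n * step^2 for n i.i.d. unit steps
        step, n_steps = 0.2, 100
        rng_seeds = range(400)
        r2 = []
        for s in rng_seeds:
            track = tt.gen_uncorrelated(step, step * n_steps, ds=0.2, seed=s)
            r2.append(np.sum((track.points[-1] - track.points[0]) ** 2))
        assert np.mean(r2) == pytest.approx(n_steps * step ** 2, rel=0.15)


class TestSearch:
    def test_pure_spiral_turn_rate(self):
        params = tt.SearchModelParams(tangent_noise=0.0,
                                      reversal_mean_spacing=math.inf,
                                      return_to_centre_rate=0.0)
        track = tt.gen_search(params, seed=7)
        h = tt.headings(track, 0.04)
        rate = np.mean(np.abs(wrap_angle(np.diff(h)))) / 0.04
        assert rate == pytest.approx(params.spiral_turn_rate, rel=1e-6)

    def test_spiral_rate_recovered_from_grand_mean(self):
        curves = [tt.mean_angle_curve(tt.gen_search(seed=s)) for s in range(100)]
        fit = tt.fit_slope(tt.grand_mean_curve(curves), (1.2, 6.4), "lin-lin")
        assert fit.slope == pytest.approx(12.0, rel=0.15)

    def test_occupancy_density_decays_with_goal_distance(self):
        pts = np.vstack([tt.gen_search(seed=s).points for s in range(100)])
        r = np.linalg.norm(pts, axis=1)
        edges = np.array([0.0, 2.0, 4.0, 8.0])
        counts, _ = np.histogram(r, bins=edges)
        density = counts / (np.pi * np.diff(edges ** 2))
        assert np.all(np.diff(density) < 0)

    def test_starts_at_goal(self):
        track = tt.gen_search(goal=(3.0, -2.0), seed=8)
        np.testing.assert_allclose(track.points[0], [3.0, -2.0])


class TestApproach:
    def test_terminates_at_goal(self):
        track = tt.gen_approach((10.0, 0.0), (0.0, 0.0), seed=9)
        assert np.linalg.norm(track.points[-1]) <= 2 * 0.04

    def test_infinite_persistence_is_straight(self):
        track = tt.gen_approach((5.0, 0.0), (0.0, 0.0), persistence=math.inf, seed=0)
        np.testing.assert_allclose(track.points[:, 1], 0.0, atol=1e-9)

    def test_straightness_decreases_with_noise(self):
        straightness = []
        for persistence in [100.0, 10.0, 2.0]:
            vals = []
            for s in range(12):
                track = tt.gen_approach((10.0, 0.0), (0.0, 0.0),
                                        persistence=persistence, seed=s)
                vals.append(10.0 / track.total_arclength)
            straightness.append(np.mean(vals))
        assert straightness[0] > straightness[1] > straightness[2]


class TestCohort:
    def test_group_sizes_sum_to_141(self, full_cohort):
        _, records, truth = full_cohort
        assert len(records) == 141
        assert len(truth) == 141
        counts = truth.groupby(["goal_type", "experience"]).size()
        assert counts[("nest", "inexperienced")] == 30
        assert counts[("nest", "experienced")] == 31
        assert counts[("feeder_sparse", "inexperienced")] == 13
        assert counts[("feeder_sparse", "experienced")] == 15
        assert counts[("feeder_plentiful", "inexperienced")] == 30
        assert counts[("feeder_plentiful", "experienced")] == 22

    def test_same_seed_byte_identical(self, small_cohort):
        cfg, records, truth = small_cohort
        again, truth2 = tt.gen_cohort(cfg)
        for a, b in zip(records, again):
            np.testing.assert_array_equal(a.points, b.points)
        assert truth.equals(truth2)

    def test_truth_matches_records(self, small_cohort):
        _, records, truth = small_cohort
        assert list(truth["animal_id"]) == [r.animal_id for r in records]
        assert (truth["split_s"] > 0).all()
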