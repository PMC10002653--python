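import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import straight_track
from larvatrack.features import (
    binned_population_summary,
    decline_slope,
    kinematics,
    navigation_index,
    peri_event_average,
    speed_turnrate_correlation,
    stitch_trajectory,
    turn_statistics,
)
from larvatrack.simulate import synthetic_speed_series

FR = 10.0


class TestKinematics:
    def test_constant_velocity_speed(self):
        x, y = straight_track(speed_mm_s=0.3)
        ks = kinematics(x, y, FR)
        assert np.allclose(ks.speed_mm_s, 0.3, atol=1e-9)
        assert np.allclose(ks.heading_deg, 0.0, atol=1e-9)

    def test_circular_path_curvature_is_inverse_radius(self):
        R = 10.0
        t = np.arange(3000) / FR
        omega = 0.3 / R  # 0.3 mm/s tangential speed
        x = 50 + R * np.cos(omega * t)
        y = 50 + R * np.sin(omega * t)
        ks = kinematics(x, y, FR)
        mid = ks.curvature_per_mm[100:-100]
        assert np.nanmean(mid) == pytest.approx(1.0 / R, rel=0.02)

    def test_stationary_track_speed_zero_curvature_missing(self):
        x = np.full(100, 5.0)
        y = np.full(100, 7.0)
        ks = kinematics(x, y, FR)
        assert np.allclose(ks.speed_mm_s, 0.0)
        assert np.isnan(ks.curvature_per_mm).all()

    def test_excluded_frames_masked_with_margin(self):
        x, y = straight_track(n_frames=200)
        exclude = np.zeros(200, bool)
        exclude[100:110] = True
        ks = kinematics(x, y, FR, exclude=exclude)
        assert np.isnan(ks.speed_mm_s[100:110]).all()
        assert not ks.valid[100:110].any()
        assert ks.valid[:80].all()


class TestNavigationIndex:
    def test_extremes_and_perpendicular(self):
        for heading, expected in [(0.0, 1.0), (180.0, -1.0), (90.0, 0.0)]:
            x, y = straight_track(heading_deg=heading)
            ks = kinematics(x, y, FR)
            nav = navigation_index(ks.speed_mm_s, ks.heading_deg, FR)
            assert nav.ni == pytest.approx(expected, abs=1e-12)

    def test_half_x_half_y_gives_half(self):
        speed = np.ones(1000)
        heading = np.concatenate([np.zeros(500), np.full(500, 90.0)])
        nav = navigation_index(speed, heading, FR)
        assert nav.ni == pytest.approx(0.5)

    def test_all_frames_below_vmin_gives_missing(self):
        nav = navigation_index(np.full(100, 0.01), np.zeros(100), FR, v_min=0.05)
        assert np.isnan(nav.ni)

    @given(st.lists(st.floats(-179.0, 180.0), min_size=20, max_size=60))
    @settings(max_examples=30, deadline=None)
    def test_bounded_and_reflection_negates(self, headings):
        h = np.asarray(headings)
        speed = np.full(len(h), 0.3)
        ni = navigation_index(speed, h, FR).ni
        assert -1.0 <= ni <= 1.0
        # reflect through the axis normal to the gradient: heading -> 180 - heading
        ni_ref = navigation_index(speed, 180.0 - h, FR).ni
        assert ni_ref == pytest.approx(-ni, abs=1e-12)


def _segments(directions):
    rows = []
    f = 0
    for d in directions:
        rows.append((0, "run", f, f + 99, None, None))
        rows.append((0, "turn", f + 100, f + 119, d, 60.0))
        f += 120
    rows.append((0, "run", f, f + 99, None, None))
    return pd.DataFrame(
        rows, columns=["animal_id", "state", "start_frame", "end_frame", "direction", "turn_size_deg"]
    )


class TestTurnStatistics:
    def test_all_left_handedness_one(self):
        segs = _segments(["left"] * 10)
        _, summary = turn_statistics(segs, 1300, FR)
        assert summary.handedness == 1.0

    def test_all_right_handedness_minus_one(self):
        segs = _segments(["right"] * 10)
        _, summary = turn_statistics(segs, 1300, FR)
        assert summary.handedness == -1.0

    def test_mixed_handedness(self):
        segs = _segments(["left"] * 6 + ["right"] * 4)
        _, summary = turn_statistics(segs, 1300, FR)
        assert summary.handedness == pytest.approx(0.2)

    def test_no_turns_handedness_missing(self):
        segs = _segments([])
        _, summary = turn_statistics(segs, 100, FR)
        assert summary.handedness is None
        assert summary.n_total == 0


class TestPeriEvent:
    def test_constant_input_no_significance(self):
        v = np.full(12000, 0.3)
        v += 0.001 * np.sin(np.arange(12000))  # nonzero variance, no effect
        res = peri_event_average(v, FR, [6000], window_min=5)
        assert res.n_events == 1
        assert (res.minute_p > 0.05).all()
        assert res.returns_to_baseline

    def test_injected_transient_detected_in_first_two_minutes(self):
        T = 36000
        events = np.arange(4000, 33000, 4000)
        pvals = []
        for seed in range(20):
            v = synthetic_speed_series(T, FR, events, rng=np.random.default_rng([seed, 42]))
            res = peri_event_average(v, FR, events, window_min=5)
            pvals.append(res.minute_p)
        med = np.median(np.vstack(pvals), axis=0)
        assert (med[:2] < 0.05).all()
        assert (med[2:] >= 0.05).all()

    def test_events_near_boundary_skipped(self):
        v = np.full(4000, 0.3)
        res = peri_event_average(v, FR, [100, 2000, 3999], window_min=5)
        assert res.n_events == 0 and res.n_skipped == 3


class TestStitching:
    def test_no_events_identity(self):
        x, y = straight_track()
        xs, ys, length_m, skipped = stitch_trajectory(x, y, [])
        assert np.array_equal(xs, x) and np.array_equal(ys, y)
        assert skipped == []

    def test_two_subpaths_stitched_additively(self):
        # 10 mm at 0.1 mm/frame, a transport jump, then 10 mm more
        x1 = np.arange(100) * 0.1
        x2 = 50.0 + np.arange(100) * 0.1
        x = np.concatenate([x1, x2])
        y = np.zeros(200)
        jump = (100, (x1[-1], 0.0), (50.0, 0.0))
        xs, ys, length_m, _ = stitch_trajectory(x, y, [jump])
        assert length_m * 1000 == pytest.approx(19.9 + 0.1, abs=0.2)
        gaps = np.hypot(np.diff(xs), np.diff(ys))
        assert gaps.max() <= 0.1 + 1e-9  # continuous at the joint

    def test_path_length_invariant_under_stitching(self):
        # crawl-frame path length must not change however the transport
        # events translate the sub-paths
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.normal(0, 0.03, 500))
        y = np.cumsum(rng.normal(0, 0.03, 500))
        exclude = np.zeros(500, bool)
        exclude[[100, 300]] = True  # manipulation frames
        _, _, raw, _ = stitch_trajectory(x, y, [], exclude=exclude)
        jumps = [(100, (x[99], y[99]), (x[100], y[100])), (300, (x[299], y[299]), (x[300], y[300]))]
        _, _, stitched, _ = stitch_trajectory(x, y, jumps, exclude=exclude)
        assert stitched == pytest.approx(raw, rel=1e-9)

    def test_missing_positions_skip_stitch(self):
        x, y = straight_track()
        _, _, _, skipped = stitch_trajectory(x, y, [(50, None, (1.0, 1.0))])
        assert skipped == [50]


class TestPopulationSummary:
    def test_identical_animals_zero_sd(self):
        v = np.full(12000, 0.3)
        out = binned_population_summary({0: v, 1: v.copy(), 2: v.copy()}, FR)
        assert np.allclose(out["sd"].dropna(), 0.0)

    def test_two_point_sd(self):
        out = binned_population_summary({0: np.full(6000, 0.2), 1: np.full(6000, 0.4)}, FR)
        assert out["mean"].iloc[0] == pytest.approx(0.3)
        assert out["sd"].iloc[0] == pytest.approx(np.std([0.2, 0.4], ddof=1), rel=1e-6)
        assert out["sd"].iloc[0] == pytest.approx(0.141, abs=0.001)

    def test_decline_slope_recovery_from_synthetic_series(self):
        t = np.arange(36000) / FR
        slope_true = -6.9e-5
        series = {a: 0.5 + slope_true * t + 0.0 * a for a in range(3)}
        out = binned_population_summary(series, FR, bin_min=10)
        assert decline_slope(out, 3600.0) == pytest.approx(slope_true, rel=1e-6)


class TestCorrelation:
    def test_identical_series_correlation_one(self):
        v = np.linspace(0.2, 0.5, 36)
        res = speed_turnrate_correlation({0: v, 1: v}, {0: v.copy(), 1: v.copy()})
        assert res.r_population == pytest.approx(1.0)
        assert res.r_individual_mean == pytest.approx(1.0)

    def test_coupled_latent_activity_recovers_rho(self):
        # shared latent drives both series with correlation ~rho
        rng = np.random.default_rng(7)
        rho = 0.5
        n_bins, n_animals = 100, 12
        speed, rate = {}, {}
        for a in range(n_animals):
            z = rng.standard_normal(n_bins)
            speed[a] = z
            rate[a] = rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(n_bins)
        res = speed_turnrate_correlation(speed, rate)
        # population-mean series shares the same rho in expectation
        se = 1.0 / np.sqrt(n_bins - 3)
        z_obs = np.arctanh(res.r_individual_mean)
        assert abs(z_obs - np.arctanh(rho)) < 2 * se

    def test_independent_noise_low_correlation(self):
        rng = np.random.default_rng(11)
        rs = []
        for _ in range(40):
            res = speed_turnrate_correlation(
                {0: rng.standard_normal(100)}, {0: rng.standard_normal(100)}
            )
            rs.append(abs(res.r_individual_mean))
        assert np.mean(np.asarray(rs) < 0.2) >= 0.9

    def test_zero_variance_series_missing(self):
        res = speed_turnrate_correlation(
            {0: np.full(20, 1.0), 1: np.arange(20.0)},
            {0: np.arange(20.0), 1: np.arange(20.0)},
        )
        assert np.isnan(res.r_per_animal[0])
        assert res.r_per_animal[1] == pytest.approx(1.0)

    def test_too_few_bins_raises(self):
        with pytest.raises(ValueError):
            speed_turnrate_correlation({0: np.arange(5.0)}, {0: np.arange(5.0)})
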