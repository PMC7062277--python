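import numpy as np
import pandas as pd
import pytest

from drivehunt import (
    build_steps,
    cumulative_distance,
    displacement_profile,
    max_speed,
    net_displacement,
    sinuosity,
)
from drivehunt.metrics import UndefinedMetricError

from conftest import make_traj


def walk_from_turns(turns, step=100.0, start_heading=0.0):
    """Path whose turning-angle sequence is exactly ``turns``."""
    headings = start_heading + np.concatenate([[0.0], np.cumsum(turns)])
    pts = np.concatenate(
        [[[0.0, 0.0]], np.cumsum(
            step * np.column_stack([np.cos(headings), np.sin(headings)]), axis=0
        )]
    )
    return make_traj(pts)


class TestBuildSteps:
    def test_collinear_lengths_and_turns(self):
        t = make_traj([(0, 0), (100, 0), (200, 0)])
        s = build_steps(t)
        np.testing.assert_allclose(s.steps["length_m"], [100, 100])
        np.testing.assert_allclose(s.steps["turn_angle_rad"].iloc[1], 0.0)
        assert np.isnan(s.steps["turn_angle_rad"].iloc[0])

    def test_gap_flag_and_no_turn_across_gap(self):
        # middle fix missing: 4-minute composite step with factor 2.0
        t = make_traj([(0, 0), (100, 0), (200, 0), (300, 0)], fix_ok=[1, 0, 1, 1])
        s = build_steps(t, nominal_interval_min=2.0, gap_tolerance_factor=2.0)
        assert len(s) == 2
        assert list(s.steps["spans_gap"]) == [False, False]
        # tighter tolerance flags the composite step and kills its angle
        s = build_steps(t, nominal_interval_min=2.0, gap_tolerance_factor=1.5)
        assert list(s.steps["spans_gap"]) == [True, False]
        assert s.steps["turn_angle_rad"].isna().all()
        assert s.n_gap_steps == 1

    def test_single_fix_gives_empty_series(self):
        t = make_traj([(0, 0)])
        s = build_steps(t)
        assert len(s) == 0

    def test_window_restriction(self):
        t = make_traj([(0, 0), (100, 0), (200, 0), (300, 0)])
        lo = t.fixes["timestamp"].iloc[1]
        hi = t.fixes["timestamp"].iloc[2]
        assert len(build_steps(t, window=(lo, hi))) == 1


class TestSinuosity:
    def test_straight_path_is_one(self):
        assert sinuosity(build_steps(make_traj([(i * 50, 0) for i in range(10)]))) == 1.0

    def test_full_reversals_give_minus_one(self):
        t = walk_from_turns([np.pi] * 5)
        assert sinuosity(build_steps(t)) == pytest.approx(-1.0)

    def test_square_path_is_zero(self):
        t = walk_from_turns([np.pi / 2] * 3)
        assert sinuosity(build_steps(t)) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_random_turns_are_brownian(self):
        rng = np.random.default_rng(6)
        turns = rng.uniform(-np.pi, np.pi, 10_000)
        t = walk_from_turns(turns)
        assert sinuosity(build_steps(t)) == pytest.approx(0.0, abs=0.02)

    def test_no_turning_angle_raises(self):
        with pytest.raises(UndefinedMetricError):
            sinuosity(build_steps(make_traj([(0, 0), (10, 0)])))

    def test_bounded(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            turns = rng.uniform(-np.pi, np.pi, 50)
            v = sinuosity(build_steps(walk_from_turns(turns)))
            assert -1.0 <= v <= 1.0


class TestMaxSpeed:
    def test_600m_in_two_minutes_is_18kmh(self):
        s = build_steps(make_traj([(0, 0), (600, 0)]))
        assert max_speed(s) == pytest.approx(18.0)

    def test_max_over_steps(self):
        s = build_steps(make_traj([(0, 0), (100, 0), (150, 0)]))
        assert max_speed(s) == pytest.approx(3.0)

    def test_empty_raises(self):
        with pytest.raises(UndefinedMetricError):
            max_speed(build_steps(make_traj([(0, 0)])))


class TestCumulativeDistance:
    def test_sums_lengths(self):
        s = build_steps(make_traj([(0, 0), (100, 0), (300, 0), (600, 0)]))
        assert cumulative_distance(s) == pytest.approx(600.0)

    def test_empty_is_zero(self):
        assert cumulative_distance(build_steps(make_traj([(0, 0)]))) == 0.0

    def test_brute_force_resummation_oracle(self):
        from drivehunt import GeneratorConfig, simulate_hunt_response
        from shapely.geometry import Point

        cfg = GeneratorConfig()
        poly = Point(0, 0).buffer(600)
        rng = np.random.default_rng(5)
        times, xy, _ = simulate_hunt_response(
            (50.0, -30.0), poly,
            pd.Timestamp("2018-01-12T10:00:00+00:00"),
            pd.Timestamp("2018-01-12T11:00:00+00:00"),
            "flee", cfg, rng,
        )
        traj = make_traj(xy, t0=times[0])
        total = cumulative_distance(build_steps(traj))
        # independent pairwise re-summation
        oracle = float(np.sum(np.hypot(*np.diff(xy, axis=0).T)))
        assert total == pytest.approx(oracle, rel=1e-9)


@pytest.mark.parametrize("angle", [0.3, 1.2, 2.5])
def test_translation_rotation_invariance(angle):
    rng = np.random.default_rng(8)
    pts = rng.normal(0, 200, (40, 2))
    R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    moved = pts @ R.T + np.array([12345.0, -6789.0])
    s0, s1 = build_steps(make_traj(pts)), build_steps(make_traj(moved))
    assert max_speed(s0) == pytest.approx(max_speed(s1))
    assert cumulative_distance(s0) == pytest.approx(cumulative_distance(s1))
    assert sinuosity(s0) == pytest.approx(sinuosity(s1))


def test_cumulative_at_least_net_displacement():
    rng = np.random.default_rng(9)
    pts = rng.normal(0, 300, (60, 2))
    s = build_steps(make_traj(pts))
    net = float(np.hypot(*(pts[-1] - pts[0])))
    assert cumulative_distance(s) >= net - 1e-9


class TestNetDisplacement:
    def test_three_four_five(self):
        t = make_traj([(300, 400)])
        d = net_displacement(t, (0, 0), [t.fixes["timestamp"].iloc[0]], 1.0)
        assert d[0] == pytest.approx(500.0)

    def test_zero_at_reference(self):
        t = make_traj([(7, 7)])
        assert net_displacement(t, (7, 7), [t.fixes["timestamp"].iloc[0]], 1.0)[0] == 0.0

    def test_undefined_outside_tolerance(self):
        t = make_traj([(0, 0)])
        far = t.fixes["timestamp"].iloc[0] + pd.Timedelta(hours=2)
        assert np.isnan(net_displacement(t, (0, 0), [far], 1.0)[0])


class TestDisplacementProfile:
    def _event(self, ind, point, hunt):
        from drivehunt.events import HuntEvent

        return HuntEvent(
            f"h:{ind}", ind, hunt.hunt_id, hunt.area_id, point,
            hunt.start, classification="fleeing",
        )

    def _hunt(self):
        from drivehunt import DriveHunt

        return DriveHunt(
            "h", "A",
            pd.Timestamp("2018-01-12T10:00:00+00:00"),
            pd.Timestamp("2018-01-12T11:00:00+00:00"),
            30, 40, 33, 12,
        )

    def test_median_of_two_events(self):
        hunt = self._hunt()
        trajs = {
            "a": make_traj([(100, 0)] * 3, t0="2018-01-12T12:00:00+00:00", interval_min=60),
            "b": make_traj([(300, 0)] * 3, t0="2018-01-12T12:00:00+00:00", interval_min=60),
        }
        evs = [self._event("a", (0.0, 0.0), hunt), self._event("b", (0.0, 0.0), hunt)]
        prof = displacement_profile(evs, trajs, {"h": hunt})
        day0 = prof[(prof.day_offset == 0) & (prof.period == "day")]
        assert day0["median_m"].iloc[0] == pytest.approx(200.0)
        assert day0["n_events"].iloc[0] == 2

    def test_stationary_animal_near_zero(self):
        hunt = self._hunt()
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 5.8, (72, 2))
        trajs = {"a": make_traj(pts, t0="2018-01-10T12:00:00+00:00", interval_min=120)}
        evs = [self._event("a", (0.0, 0.0), hunt)]
        prof = displacement_profile(evs, trajs, {"h": hunt})
        assert (prof["median_m"] < 3 * 5.8).all()

    def test_baseline_phase_labelling(self):
        hunt = self._hunt()
        trajs = {"a": make_traj([(0, 0)] * 130, t0="2018-01-10T00:00:00+00:00", interval_min=60)}
        evs = [self._event("a", (0.0, 0.0), hunt)]
        prof = displacement_profile(evs, trajs, {"h": hunt})
        pre = prof[prof.day_offset < 0]
        assert (pre["phase"] == "baseline").all()
        assert (prof[prof.day_offset > 0]["phase"] == "response").all()
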