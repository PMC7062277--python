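import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from drivehunt import (
    AnalysisConfig,
    DriveHunt,
    HuntedArea,
    classify_event,
    compute_events,
    delayed_distance,
    detect_events,
    events_table,
    immediate_distance,
)

from conftest import make_traj

SQUARE = Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])


def square_area(aid="A"):
    return HuntedArea(aid, SQUARE, 0.2)


def hunt(start="2018-01-12T10:00:00+00:00", minutes=60):
    s = pd.Timestamp(start)
    return DriveHunt("h1", "A", s, s + pd.Timedelta(minutes=minutes), 30, 40, 33, 12)


class TestDetectEvents:
    def test_inside_at_start_is_event(self):
        t = make_traj([(500, 500)] * 5, t0="2018-01-12T10:00:00+00:00")
        evs = detect_events({"a": t}, [hunt()], {"A": square_area()})
        assert len(evs) == 1
        assert evs[0].encounter_point == (500.0, 500.0)

    def test_outside_at_start_entering_later_is_not_event(self):
        pts = [(1050, 500)] + [(500, 500)] * 10
        t = make_traj(pts, t0="2018-01-12T10:00:00+00:00")
        assert detect_events({"a": t}, [hunt()], {"A": square_area()}) == []

    def test_two_inside_one_outside(self):
        trajs = {
            "a": make_traj([(10, 10)] * 3, t0="2018-01-12T10:00:00+00:00"),
            "b": make_traj([(900, 900)] * 3, t0="2018-01-12T10:00:00+00:00"),
            "c": make_traj([(-50, 500)] * 3, t0="2018-01-12T10:00:00+00:00"),
        }
        evs = detect_events(trajs, [hunt()], {"A": square_area()})
        assert sorted(e.individual_id for e in evs) == ["a", "b"]

    def test_no_fix_near_start_skipped(self):
        t = make_traj([(500, 500)] * 3, t0="2018-01-12T10:05:00+00:00")
        assert detect_events({"a": t}, [hunt()], {"A": square_area()}) == []

    def test_order_independent(self):
        trajs = {
            k: make_traj([(400 + i, 400)] * 3, t0="2018-01-12T10:00:00+00:00", individual=k)
            for i, k in enumerate("abc")
        }
        ids1 = [e.event_id for e in detect_events(trajs, [hunt()], {"A": square_area()})]
        rev = dict(reversed(list(trajs.items())))
        ids2 = [e.event_id for e in detect_events(rev, [hunt()], {"A": square_area()})]
        assert ids1 == ids2


class TestClassify:
    def _event(self, traj):
        return detect_events({"a": traj}, [hunt()], {"A": square_area()})[0]

    def test_exit_mid_hunt_is_fleeing(self):
        pts = [(500, 500)] * 5 + [(1200, 500)] + [(500, 500)] * 25
        t = make_traj(pts, t0="2018-01-12T10:00:00+00:00")
        ev = self._event(t)
        assert classify_event(ev, t, hunt(), square_area()) == "fleeing"

    def test_tortuous_inside_is_staying(self):
        rng = np.random.default_rng(1)
        pts = 500 + rng.normal(0, 80, (31, 2))
        t = make_traj(pts, t0="2018-01-12T10:00:00+00:00")
        ev = self._event(t)
        assert classify_event(ev, t, hunt(), square_area()) == "staying"

    def test_boundary_fix_counts_as_inside(self):
        pts = [(500, 500)] * 10 + [(1000.0, 500.0)] + [(500, 500)] * 20
        t = make_traj(pts, t0="2018-01-12T10:00:00+00:00")
        ev = self._event(t)
        assert classify_event(ev, t, hunt(), square_area()) == "staying"

    def test_too_few_fixes_unclassifiable(self):
        pts = [(500, 500)] * 31
        ok = [True] + [False] * 30
        t = make_traj(pts, t0="2018-01-12T10:00:00+00:00", fix_ok=ok)
        ev = self._event(t)
        assert classify_event(ev, t, hunt(), square_area()) is None

    def test_under_half_expected_fixes_unclassifiable(self):
        # 10 valid fixes of ~31 expected in the hour
        pts = [(500, 500)] * 31
        ok = [i < 10 for i in range(31)]
        t = make_traj(pts, t0="2018-01-12T10:00:00+00:00", fix_ok=ok)
        ev = self._event(t)
        assert classify_event(ev, t, hunt(), square_area()) is None


class TestDistances:
    def test_thirty_straight_steps(self):
        pts = [(500 + 10 * i, 500) for i in range(31)]
        t = make_traj(pts, t0="2018-01-12T10:00:00+00:00")
        ev = detect_events({"a": t}, [hunt()], {"A": square_area()})[0]
        assert immediate_distance(ev, t, hunt()) == pytest.approx(300.0)

    def test_stationary_bounded_by_noise(self):
        rng = np.random.default_rng(2)
        pts = 500 + rng.normal(0, 5.8, (31, 2))
        t = make_traj(pts, t0="2018-01-12T10:00:00+00:00")
        ev = detect_events({"a": t}, [hunt()], {"A": square_area()})[0]
        d = immediate_distance(ev, t, hunt())
        assert d < 3 * 5.8 * 30

    def test_delayed_hourly_sum_to_dawn(self):
        # hunt 16:00-17:00 UTC (17:00-18:00 Paris); hourly 500 m steps
        h = hunt(start="2018-01-12T16:00:00+00:00")
        # dawn = 08:00 Paris = 07:00 UTC next day -> grid start 16:00 ... 07:00
        n = 16
        pts = [(500 + 500 * i, 500) for i in range(n)]
        t = make_traj(pts, t0="2018-01-12T16:00:00+00:00", interval_min=60)
        ev = detect_events({"a": t}, [h], {"A": square_area()})[0]
        d = delayed_distance(ev, t, h)
        assert d == pytest.approx(500.0 * (n - 1))
        assert ev.delayed_complete

    def test_delayed_from_hunt_end_switch(self):
        h = hunt(start="2018-01-12T16:00:00+00:00")
        pts = [(500 + 500 * i, 500) for i in range(16)]
        t = make_traj(pts, t0="2018-01-12T16:00:00+00:00", interval_min=60)
        ev = detect_events({"a": t}, [h], {"A": square_area()})[0]
        cfg = AnalysisConfig(delayed_from="hunt_end")
        d = delayed_distance(ev, t, h, cfg)
        assert d == pytest.approx(500.0 * 14)  # one intra-hunt hourly step fewer

    def test_truncated_trajectory_flagged_partial(self):
        h = hunt(start="2018-01-12T16:00:00+00:00")
        pts = [(500 + 500 * i, 500) for i in range(4)]
        t = make_traj(pts, t0="2018-01-12T16:00:00+00:00", interval_min=60)
        ev = detect_events({"a": t}, [h], {"A": square_area()})[0]
        delayed_distance(ev, t, h)
        assert not ev.delayed_complete


class TestLabelRecovery:
    def test_noise_off_classification_is_exact(self):
        from drivehunt import simulate_events

        sim = simulate_events(40, rng=11, noise=False, with_delayed=False)
        evs = compute_events(sim.trajectories, sim.hunts, sim.areas)
        tab = events_table(evs).set_index("event_id")
        truth = sim.ground_truth.events.set_index("event_id")
        joined = tab.join(truth, how="inner", rsuffix="_t")
        assert len(joined) == 40
        got = joined["classification"].map({"fleeing": "flee", "staying": "stay"})
        assert (got == joined["branch"]).all()

    def test_default_noise_recovery(self, events_sim_small):
        sim = events_sim_small
        evs = compute_events(sim.trajectories, sim.hunts, sim.areas)
        tab = events_table(evs).set_index("event_id")
        truth = sim.ground_truth.events.set_index("event_id")
        joined = tab.join(truth, how="inner", rsuffix="_t")
        got = joined["classification"].map({"fleeing": "flee", "staying": "stay"})
        assert (got == joined["branch"]).mean() >= 0.95


def test_covariates_attached(events_sim_small):
    sim = events_sim_small
    evs = compute_events(sim.trajectories, sim.hunts, sim.areas)
    tab = events_table(evs)
    assert tab["bush"].between(0, 1).all()
    assert tab["dogs_per_ha"].between(0.1, 1.1).all()
    assert tab["gunshots"].between(10, 85).all()
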