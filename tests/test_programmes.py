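"""Training-programme translation and damage attribution."""

import numpy as np
import pytest

from osteofatigue import BoneState, LoadingSchedule, simulate
from osteofatigue.programmes import (
    SpeedLoadMap,
    TrainingPhase,
    Workout,
    attribute_damage,
    cycles_per_day,
    default_programme,
    expand_programme,
    schedule_from_programme,
)


@pytest.fixture(scope="module")
def speed_map() -> SpeedLoadMap:
    return SpeedLoadMap()


class TestSpeedLoadMap:
    def test_printed_anchors(self, speed_map):
        sigma, eps = speed_map.load_at(14.0)
        assert (sigma, eps) == (81.1, 0.2974)
        sigma0, _ = speed_map.load_at(0.0)
        assert sigma0 == 30.0
        sigma16, _ = speed_map.load_at(16.0)
        assert sigma16 == 90.0

    def test_pressure_monotone_in_speed(self, speed_map):
        speeds = np.linspace(0.0, 16.0, 30)
        sigmas = [speed_map.load_at(s)[0] for s in speeds]
        assert all(b >= a for a, b in zip(sigmas, sigmas[1:]))

    def test_no_extrapolation(self, speed_map):
        with pytest.raises(ValueError):
            speed_map.load_at(20.0)
        with pytest.raises(ValueError):
            speed_map.stride_length(25.0)

    def test_invalid_anchor_order_rejected(self):
        with pytest.raises(ValueError):
            SpeedLoadMap(load_anchors=((0.0, 50.0, 0.02), (14.0, 30.0, 0.3)))


class TestCyclesPerDay:
    def test_reference_workload(self, speed_map):
        # 8000 m every 30 days at 14 m/s is the printed 43.7 cycles/day anchor
        assert cycles_per_day(8000.0 / 30.0, 14.0, speed_map) == pytest.approx(
            43.7, abs=0.05
        )

    def test_weekly_gallop_volume(self, speed_map):
        # a typical 1800 m/week gallop volume: approximately 40 cycles/day
        cycles = cycles_per_day(1800.0 / 7.0, 14.0, speed_map)
        assert cycles == pytest.approx(40.0, rel=0.15)

    def test_zero_distance(self, speed_map):
        assert cycles_per_day(0.0, 10.0, speed_map) == 0.0


class TestScheduleFromProgramme:
    def test_rest_phase_single_segment(self, speed_map):
        sched, days = schedule_from_programme([TrainingPhase("rest", 10)], speed_map)
        assert len(sched.segments) == 1
        start, end, cond = sched.segments[0]
        assert (start, end) == (0.0, 10.0)
        assert cond.sigma == 30.0 and cond.vn == 0.0
        assert all(len(d) == 0 for d in days)

    def test_daily_reference_workout(self, speed_map):
        phase = TrainingPhase(
            "race-fit", 30, (Workout(14.0, 8000.0 / 30.0, "day"),)
        )
        sched, _ = schedule_from_programme([phase], speed_map)
        assert len(sched.segments) == 1
        cond = sched.segments[0][2]
        assert cond.sigma == 81.1
        assert cond.vn == pytest.approx(43.7, abs=0.05)

    def test_concatenation_invariance(self, speed_map):
        phase = TrainingPhase("progressive", 7, (Workout(7.5, 2000.0, "day"),))
        two, _ = schedule_from_programme([phase, phase], speed_map)
        one, _ = schedule_from_programme(
            [TrainingPhase("progressive", 14, (Workout(7.5, 2000.0, "day"),))], speed_map
        )
        assert two == one

    def test_weekly_workouts_fall_on_week_day(self, speed_map):
        phase = TrainingPhase("progressive", 14, (Workout(13.8, 800.0, "week"),))
        days = expand_programme([phase], week_day=2)
        loaded = [i for i, d in enumerate(days) if d]
        assert loaded == [2, 9]

    def test_dominant_speed_sets_pressure_cycles_aggregate(self, speed_map):
        phase = TrainingPhase(
            "race-fit", 1,
            (Workout(7.5, 2000.0, "day"), Workout(16.0, 400.0, "day")),
        )
        sched, _ = schedule_from_programme([phase], speed_map)
        cond = sched.segments[0][2]
        assert cond.sigma == 90.0
        expected_vn = cycles_per_day(2000.0, 7.5, speed_map) + cycles_per_day(
            400.0, 16.0, speed_map
        )
        assert cond.vn == pytest.approx(expected_vn)

    def test_rest_phase_rejects_fast_work(self):
        with pytest.raises(ValueError):
            TrainingPhase("rest", 10, (Workout(10.0, 500.0, "day"),))


class TestAttribution:
    def _run(self, phases, params, speed_map, initial=BoneState(0.8, 0.0)):
        sched, days = schedule_from_programme(phases, speed_map)
        res = simulate(sched, initial, params)
        return res, days

    def test_single_speed_holds_all_damage(self, fitted, speed_map):
        phases = [TrainingPhase("race-fit", 20, (Workout(14.0, 1500.0, "day"),))]
        res, days = self._run(phases, fitted, speed_map)
        att = attribute_damage(res, days, fitted, speed_map)
        assert set(att.by_speed["speed"]) == {14.0}
        assert att.total_damage == pytest.approx(float(att.by_speed["damage"].sum()))

    def test_zero_distance_days_contribute_nothing(self, fitted, speed_map):
        phases = [
            TrainingPhase("race-fit", 5, (Workout(14.0, 1500.0, "day"),)),
            TrainingPhase("rest", 5),
        ]
        res, days = self._run(phases, fitted, speed_map)
        att = attribute_damage(res, days, fitted, speed_map)
        assert att.daily["day"].max() == 4

    def test_two_speed_day_per_cycle_ratio(self, fitted):
        # two workouts in one day, 10 cycles at 90 MPa vs 100 cycles at
        # 60 MPa: the stiffness factor cancels within a day, leaving
        # 0.1 * 10^(30 / 14.1) = 13.42 (per-cycle fatigue law)
        speed_map = SpeedLoadMap(
            load_anchors=((0.0, 30.0, 0.0225), (10.0, 60.0, 0.29), (16.0, 90.0, 0.2974)),
            stride_anchors=((0.0, 1.0), (16.0, 1.0)),
        )
        phases = [
            TrainingPhase(
                "race-fit", 1,
                (Workout(16.0, 10.0, "day"), Workout(10.0, 100.0, "day")),
            )
        ]
        res, days = self._run(phases, fitted, speed_map)
        att = attribute_damage(res, days, fitted, speed_map)
        damage = att.by_speed.set_index("speed")["damage"]
        expected = 0.1 * 10.0 ** (30.0 / 14.1)
        assert damage[16.0] / damage[10.0] == pytest.approx(expected, rel=1e-9)

    def test_conservation_against_trace(self, fitted, speed_map):
        # single speed per day: attributed damage must integrate to the
        # trajectory's own formation term
        phases = [TrainingPhase("race-fit", 40, (Workout(14.0, 2000.0, "day"),))]
        res, days = self._run(phases, fitted, speed_map)
        att = attribute_damage(res, days, fitted, speed_map)
        integral = np.trapezoid(res.trace["Df"], res.trace["day"])
        assert att.total_damage == pytest.approx(float(integral), rel=0.01)

    def test_removing_fast_work_reduces_damage(self, fitted, speed_map):
        with_fast = [
            TrainingPhase(
                "race-fit", 30,
                (Workout(7.5, 2000.0, "day"), Workout(16.0, 600.0, "week")),
            )
        ]
        without = [TrainingPhase("race-fit", 30, (Workout(7.5, 2000.0, "day"),))]
        res_f, days_f = self._run(with_fast, fitted, speed_map)
        res_w, days_w = self._run(without, fitted, speed_map)
        att_f = attribute_damage(res_f, days_f, fitted, speed_map)
        att_w = attribute_damage(res_w, days_w, fitted, speed_map)
        assert att_f.total_damage > att_w.total_damage
        assert res_f.D[-1] > res_w.D[-1]

    def test_cumulative_series_non_decreasing(self, fitted, speed_map):
        res, days = self._run(default_programme(1), fitted, speed_map,
                              initial=BoneState(0.61, 0.0))
        att = attribute_damage(res, days, fitted, speed_map)
        cum = att.cumulative()
        for _, grp in cum.groupby("speed"):
            assert np.all(np.diff(grp["cum_damage"]) >= -1e-15)
            assert np.all(np.diff(grp["cum_distance_m"]) >= -1e-9)
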