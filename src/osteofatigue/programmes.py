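"""Training programmes: speed/distance workouts mapped to bone loading.

A programme is a list of phases (rest, pre-training, progressive, race-fit),
each holding daily or weekly workouts at a speed (m/s) and distance (m).  A
:class:`SpeedLoadMap` turns speed into joint contact pressure and strain
rate, and distance into loading cycles through the stride length.  The map's
defaults interpolate linearly between three printed anchors — 30 MPa at rest,
81.1 MPa / 0.2974 1/s at 14.0 m/s, 90 MPa at racing speed (16.0 m/s) — and a
stride length of 6.103 m at 14.0 m/s (so 8000 m per 30 days gives exactly
43.7 cycles/day).  Everything in the map is an explicit, overridable table:
speeds outside the anchor range are an error, never an extrapolation.

For the ODE, each day collapses to one loading condition: the highest-speed
workout's pressure and strain rate (the dominant adaptation signal) with
cycles aggregated across all workouts.  Damage attribution, by contrast, is
additive per cycle, so each workout contributes with its own pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .model import BoneState, LoadingCondition, damage_per_cycle
from .params import ModelParameters
from .simulation import LoadingSchedule, SimulationResult, rest_strain_rate

__all__ = [
    "Workout",
    "TrainingPhase",
    "SpeedLoadMap",
    "DamageAttribution",
    "cycles_per_day",
    "expand_programme",
    "schedule_from_programme",
    "attribute_damage",
    "default_programme",
]

#: Canter threshold: rest phases must contain no workout at or above this speed.
_FAST_SPEED = 7.5


@dataclass(frozen=True)
class Workout:
    """One workout: speed (m/s), distance (m), performed per day or per week.

    Weekly workouts fall on ``weekday`` (0-6 within each phase week) when
    given, else on the schedule-wide default.
    """

    speed: float
    distance: float
    per: Literal["day", "week"] = "day"
    weekday: int | None = None

    def __post_init__(self) -> None:
        if not self.speed > 0:
            raise ValueError(f"speed must be > 0, got {self.speed}")
        if self.distance < 0:
            raise ValueError(f"distance must be >= 0, got {self.distance}")
        if self.per not in ("day", "week"):
            raise ValueError(f"per must be 'day' or 'week', got {self.per!r}")
        if self.weekday is not None and not 0 <= self.weekday <= 6:
            raise ValueError("weekday must be in 0..6")


@dataclass(frozen=True)
class TrainingPhase:
    """A phase of a preparation: kind, duration in days, workouts."""

    kind: Literal["rest", "pre-training", "progressive", "race-fit"]
    duration: int
    workouts: tuple[Workout, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("rest", "pre-training", "progressive", "race-fit"):
            raise ValueError(f"unknown phase kind {self.kind!r}")
        if not self.duration > 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.kind == "rest" and any(w.speed >= _FAST_SPEED for w in self.workouts):
            raise ValueError("rest phases cannot contain fast (>= 7.5 m/s) workouts")


def _default_load_anchors(params: ModelParameters | None = None):
    eps_rest = rest_strain_rate(params)
    # Strain rate at 16 m/s linearly extends the (rest, 14 m/s) trend.
    eps_16 = 0.2974 + 2.0 * (0.2974 - eps_rest) / 14.0
    return (
        (0.0, 30.0, eps_rest),
        (14.0, 81.1, 0.2974),
        (16.0, 90.0, eps_16),
    )


@dataclass(frozen=True)
class SpeedLoadMap:
    """Piecewise-linear speed -> (pressure, strain rate) and speed -> stride maps.

    ``load_anchors``: rows of (speed m/s, sigma MPa, strain_rate 1/s), sorted,
    pressure non-decreasing in speed.  ``stride_anchors``: rows of
    (speed m/s, stride length m).  Queries outside the anchored speed range
    raise — the relations are empirical and are not extrapolated.
    """

    load_anchors: tuple[tuple[float, float, float], ...] = field(
        default_factory=_default_load_anchors
    )
    stride_anchors: tuple[tuple[float, float], ...] = (
        (0.0, 1.0),      # walk
        (7.5, 5.5),      # canter
        (14.0, 6.103),   # gallop: fixed so 8000 m / 30 days -> 43.7 cycles/day
        (16.7, 6.9),     # racing
    )

    def __post_init__(self) -> None:
        speeds = [row[0] for row in self.load_anchors]
        sigmas = [row[1] for row in self.load_anchors]
        if sorted(speeds) != speeds or len(set(speeds)) != len(speeds):
            raise ValueError("load anchor speeds must be strictly increasing")
        if any(s2 < s1 for s1, s2 in zip(sigmas, sigmas[1:])):
            raise ValueError("pressure must be non-decreasing in speed")

    def _check_range(self, speed: float, speeds: Sequence[float]) -> None:
        if not speeds[0] <= speed <= speeds[-1]:
            raise ValueError(
                f"speed {speed} m/s outside the anchored range "
                f"[{speeds[0]}, {speeds[-1]}]; extend the map rather than extrapolate"
            )

    def load_at(self, speed: float) -> tuple[float, float]:
        """(sigma MPa, strain rate 1/s) at a speed, by linear interpolation."""
        speeds = [row[0] for row in self.load_anchors]
        self._check_range(speed, speeds)
        sigma = float(np.interp(speed, speeds, [row[1] for row in self.load_anchors]))
        eps = float(np.interp(speed, speeds, [row[2] for row in self.load_anchors]))
        return sigma, eps

    def stride_length(self, speed: float) -> float:
        """Stride length (m) at a speed, by linear interpolation."""
        speeds = [row[0] for row in self.stride_anchors]
        self._check_range(speed, speeds)
        stride = float(np.interp(speed, speeds, [row[1] for row in self.stride_anchors]))
        if stride <= 0:
            raise ValueError(f"configured stride length at {speed} m/s is non-positive")
        return stride


def cycles_per_day(distance_per_day: float, speed: float, speed_map: SpeedLoadMap) -> float:
    """Loading cycles (strides) per day for a daily distance at one speed."""
    if distance_per_day < 0 or speed < 0:
        raise ValueError("distance and speed must be non-negative")
    if distance_per_day == 0:
        return 0.0
    return distance_per_day / speed_map.stride_length(speed)


def expand_programme(
    phases: Sequence[TrainingPhase],
    week_day: int = 3,
    fast_days_exclusive: bool = True,
) -> list[list[Workout]]:
    """Per-day workout lists for a programme.

    Daily workouts occur every day of their phase; weekly workouts fall on
    their own weekday (0-6, counted within each phase's weeks) or on
    ``week_day`` when unset.  With ``fast_days_exclusive`` (the default),
    a weekly workout replaces that day's routine daily work — the usual
    structure of a fast-work day, and necessary because the day's single
    ODE loading condition charges every cycle at the fastest workout's
    pressure.
    """
    if not 0 <= week_day <= 6:
        raise ValueError("week_day must be in 0..6")
    days: list[list[Workout]] = []
    for phase in phases:
        for d in range(phase.duration):
            weekly = [
                w for w in phase.workouts
                if w.per == "week"
                and d % 7 == (w.weekday if w.weekday is not None else week_day)
            ]
            daily = [w for w in phase.workouts if w.per == "day"]
            if weekly and fast_days_exclusive:
                days.append(weekly)
            else:
                days.append(daily + weekly)
    return days


def schedule_from_programme(
    phases: Sequence[TrainingPhase],
    speed_map: SpeedLoadMap | None = None,
    week_day: int = 3,
    fast_days_exclusive: bool = True,
) -> tuple[LoadingSchedule, list[list[Workout]]]:
    """Translate a programme into a piecewise-constant loading schedule.

    Each day's condition takes sigma and strain rate from that day's
    highest-speed workout and aggregates cycles over all workouts; workout-free
    days sit at the rest condition.  Returns the schedule together with the
    per-day workout lists (needed later for damage attribution).
    """
    speed_map = speed_map or SpeedLoadMap()
    day_workouts = expand_programme(
        phases, week_day=week_day, fast_days_exclusive=fast_days_exclusive
    )
    rest_sigma, rest_eps = speed_map.load_at(0.0)

    conditions: list[LoadingCondition] = []
    for todays in day_workouts:
        if not todays:
            conditions.append(LoadingCondition(rest_sigma, rest_eps, 0.0))
            continue
        dominant = max(todays, key=lambda w: w.speed)
        sigma, eps = speed_map.load_at(dominant.speed)
        vn = sum(cycles_per_day(w.distance, w.speed, speed_map) for w in todays)
        conditions.append(LoadingCondition(sigma, eps, vn))

    # Merge consecutive identical days into segments.
    pieces: list[tuple[float, LoadingCondition]] = []
    for cond in conditions:
        if pieces and pieces[-1][1] == cond:
            pieces[-1] = (pieces[-1][0] + 1.0, cond)
        else:
            pieces.append((1.0, cond))
    return LoadingSchedule.from_durations(pieces), day_workouts


@dataclass
class DamageAttribution:
    """Distance and damage per speed bin, daily and cumulative."""

    daily: pd.DataFrame        # columns: day, speed, distance_m, damage
    by_speed: pd.DataFrame     # columns: speed, distance_m, damage

    @property
    def total_damage(self) -> float:
        return float(self.daily["damage"].sum())

    @property
    def total_distance(self) -> float:
        return float(self.daily["distance_m"].sum())

    def cumulative(self) -> pd.DataFrame:
        """Per-speed cumulative series over days (long format)."""
        out = self.daily.sort_values(["speed", "day"]).copy()
        grouped = out.groupby("speed", sort=True)
        out["cum_distance_m"] = grouped["distance_m"].cumsum()
        out["cum_damage"] = grouped["damage"].cumsum()
        return out.reset_index(drop=True)


def attribute_damage(
    result: SimulationResult,
    day_workouts: Sequence[Sequence[Workout]],
    params: ModelParameters,
    speed_map: SpeedLoadMap | None = None,
) -> DamageAttribution:
    """Attribute simulated damage formation to workout speed bins.

    Per workout and day: damage = vD(sigma_workout, E(day)) * cycles, with the
    stiffness taken from the simulation's own trace (interpolated at the day's
    midpoint) so no physics is recomputed.  Days after a failure contribute
    nothing (the simulation has stopped).
    """
    speed_map = speed_map or SpeedLoadMap()
    trace = result.trace
    if len(trace) < 2 and any(len(d) for d in day_workouts):
        raise ValueError("simulation trace too short for the given workout days")
    t_end = float(result.times[-1])

    rows = []
    for day, todays in enumerate(day_workouts):
        mid = day + 0.5
        if mid > t_end:
            break
        E_day = float(np.interp(mid, trace["day"].to_numpy(), trace["E"].to_numpy()))
        for w in todays:
            sigma_w, _ = speed_map.load_at(w.speed)
            cycles = cycles_per_day(w.distance, w.speed, speed_map)
            vD = damage_per_cycle(sigma_w, E_day, params)
            rows.append((day, w.speed, w.distance, vD * cycles))

    daily = pd.DataFrame(rows, columns=["day", "speed", "distance_m", "damage"])
    by_speed = (
        daily.groupby("speed", as_index=False)[["distance_m", "damage"]].sum()
        if len(daily)
        else pd.DataFrame(columns=["speed", "distance_m", "damage"])
    )
    return DamageAttribution(daily=daily, by_speed=by_speed)


def default_programme(preparations: int = 4) -> list[TrainingPhase]:
    """A synthetic demonstration preparation cycle (rest, pre-training,
    progressive, race-fit), repeated.

    The phase durations and workout volumes are a plausible reconstruction of
    an Australian metropolitan programme shape, not a surveyed programme:
    roughly 7 weeks rest, 4 weeks pre-training, 9 weeks progressive and 8
    weeks race-fit per preparation, daily canter volume, and two weekly
    fast-work days (slow/fast gallop and racing speed on separate weekdays)
    that step up across phases.
    """
    prep = [
        TrainingPhase("rest", 49),
        TrainingPhase("pre-training", 28, (Workout(5.0, 2000.0, "day"),)),
        TrainingPhase(
            "progressive", 63,
            (
                Workout(7.5, 2400.0, "day"),
                Workout(13.8, 800.0, "week", weekday=1),
                Workout(16.0, 400.0, "week", weekday=4),
            ),
        ),
        TrainingPhase(
            "race-fit", 56,
            (
                Workout(7.5, 2000.0, "day"),
                Workout(13.8, 1000.0, "week", weekday=1),
                Workout(16.0, 800.0, "week", weekday=4),
            ),
        ),
    ]
    return prep * preparations
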