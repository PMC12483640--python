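"""Integration of the bone adaptation/damage ODE under piecewise loading.

Loading is piecewise constant in time (a :class:`LoadingSchedule`); the
integrator restarts at every segment boundary so the discontinuity never sits
inside a solver step.  Failure (damage reaching 1) is located by the solver's
event machinery and terminates the run, matching the interpretation of
``D* = 1`` as local failure of the bone pocket.

Default loading conditions
--------------------------
``rest_loading()``     sigma = 30 MPa, no damage-relevant cycles; the strain
                       rate is back-calculated so the rest signal is
                       psi = 0.31 MPa on race-adapted bone (fBM = 0.9).
``training_loading()`` sigma = 81.1 MPa, strain rate 0.2974 1/s, 43.7
                       cycles/day — the reference gallop-training workload
                       (14 m/s, 8000 m per 30 days).
``race_loading()``     sigma = 90 MPa, otherwise as training: the
                       high-workload / racing proxy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    BoneState,
    LoadingCondition,
    RateBundle,
    model_rhs,
)
from .params import ModelParameters

__all__ = [
    "LoadingSchedule",
    "SimulationResult",
    "SteadyStateResult",
    "TimeToFailureResult",
    "simulate",
    "steady_state",
    "time_to_failure",
    "rest_strain_rate",
    "rest_loading",
    "training_loading",
    "race_loading",
]

#: Upper clip for fBM inside the right-hand side, keeping Sv defined.
_FBM_MAX = 1.0 - 1e-9
_FBM_MIN = 1e-9

#: psi at rest on race-adapted bone (MPa), used to back-calculate the rest
#: strain rate, which is not directly observable.
_PSI_REST = 0.31
_SIGMA_REST = 30.0


def rest_strain_rate(params: ModelParameters | None = None, fBM: float = 0.9) -> float:
    """Strain rate (1/s) at rest, chosen so psi(sigma=30, fBM=0.9) = 0.31 MPa.

    Solves E0 * eps^gammaE * fBM^3 = sigma^2 / (2 psi) for eps; about
    0.0225 1/s with the default stiffness law.
    """
    params = params or ModelParameters()
    E_target = _SIGMA_REST**2 / (2.0 * _PSI_REST)
    return (E_target / (params.E0 * fBM**3)) ** (1.0 / params.gammaE)


def rest_loading(params: ModelParameters | None = None) -> LoadingCondition:
    """Rest: 30 MPa proxy load, no damage-relevant cycles."""
    return LoadingCondition(sigma=30.0, strain_rate=rest_strain_rate(params), vn=0.0)


def training_loading() -> LoadingCondition:
    """Reference gallop training workload (14 m/s, 8000 m per 30 days)."""
    return LoadingCondition(sigma=81.1, strain_rate=0.2974, vn=43.7)


def race_loading() -> LoadingCondition:
    """High-workload / racing proxy."""
    return LoadingCondition(sigma=90.0, strain_rate=0.2974, vn=43.7)


@dataclass(frozen=True)
class LoadingSchedule:
    """Contiguous, non-overlapping loading segments starting at day 0."""

    segments: tuple[tuple[float, float, LoadingCondition], ...]

    def __post_init__(self) -> None:
        if self.segments:
            t = 0.0
            for start, end, _ in self.segments:
                if not math.isclose(start, t, abs_tol=1e-9):
                    raise ValueError(
                        f"segments must be contiguous from day 0; got start {start}, expected {t}"
                    )
                if not end > start:
                    raise ValueError(f"segment [{start}, {end}] has non-positive duration")
                t = end

    @classmethod
    def constant(cls, loading: LoadingCondition, duration: float) -> "LoadingSchedule":
        if duration == 0:
            return cls(segments=())
        return cls(segments=((0.0, float(duration), loading),))

    @classmethod
    def from_durations(
        cls, pieces: Sequence[tuple[float, LoadingCondition]]
    ) -> "LoadingSchedule":
        """Build a schedule from (duration, loading) pieces in order.

        Zero-duration pieces are dropped; negative durations are an error.
        """
        segments, t = [], 0.0
        for duration, loading in pieces:
            if duration < 0:
                raise ValueError(f"negative duration {duration}")
            if duration == 0:
                continue
            segments.append((t, t + float(duration), loading))
            t += float(duration)
        return cls(segments=tuple(segments))

    @property
    def total_duration(self) -> float:
        return self.segments[-1][1] if self.segments else 0.0

    def loading_at(self, t: float) -> LoadingCondition:
        for start, end, loading in self.segments:
            if start <= t < end:
                return loading
        if self.segments and math.isclose(t, self.total_duration):
            return self.segments[-1][2]
        raise ValueError(f"day {t} is outside the schedule [0, {self.total_duration}]")


@dataclass
class SimulationResult:
    """Trajectories on a common time grid plus a full rate trace."""

    times: np.ndarray
    fBM: np.ndarray
    D: np.ndarray
    trace: pd.DataFrame        # columns: day, fBM, D, Sv, E, psi, AOBL, AOCL, Df, Dr
    failure_day: float | None
    terminated_early: bool
    clipped: bool = False      # fBM hit its numerical bounds during the run

    @property
    def final_state(self) -> BoneState:
        return BoneState(fBM=float(self.fBM[-1]), D=min(float(self.D[-1]), 1.0))


def _rhs_arrays(t: float, y: np.ndarray, loading: LoadingCondition,
                params: ModelParameters) -> list[float]:
    # Fast scalar RHS used by the integrator; mirrors model_rhs but avoids
    # dataclass allocation.  fBM is clipped into (0, 1) so Sv and E stay defined.
    f = min(max(y[0], _FBM_MIN), _FBM_MAX)
    D = max(y[1], 0.0)
    p = params
    u = 1.0 - f
    Sv = p.a * math.sqrt(u) * (1.0 - p.b * u)
    E = p.E0 * loading.strain_rate**p.gammaE * f**3
    psi = loading.sigma**2 / (2.0 * E)
    hB = 0.0 if psi == 0.0 else psi**p.gammaB / (p.deltaB**p.gammaB + psi**p.gammaB)
    hC = 0.0 if psi == 0.0 else psi**p.gammaC / (p.deltaC**p.gammaC + psi**p.gammaC)
    AOBL = p.AOBL_min + (p.AOBL_max - p.AOBL_min) * hB
    AOCL = p.AOCL_max - (p.AOCL_max - p.AOCL_min) * hC
    vD = 10.0 ** ((loading.sigma - p.sigma0) / p.sigma1) * p.Enom / E
    Df = vD * loading.vn
    Dr = (AOBL + (p.Fs - 1.0) * AOCL) * p.alpha * Sv * D / f
    return [(AOBL - AOCL) * p.alpha * Sv, Df - Dr]


def _failure_event(t: float, y: np.ndarray, *args) -> float:
    return y[1] - 1.0


_failure_event.terminal = True  # type: ignore[attr-defined]
_failure_event.direction = 1.0  # type: ignore[attr-defined]


def _bundle_rows(times: np.ndarray, fBM: np.ndarray, D: np.ndarray,
                 loadings: list[LoadingCondition], params: ModelParameters) -> pd.DataFrame:
    rows = []
    for t, f, d, ld in zip(times, fBM, D, loadings):
        state = BoneState(fBM=min(max(f, _FBM_MIN), _FBM_MAX), D=min(max(d, 0.0), 1.0))
        b: RateBundle = model_rhs(t, state, ld, params)
        rows.append((t, f, d, b.Sv, b.E, b.psi, b.AOBL, b.AOCL, b.Df, b.Dr))
    return pd.DataFrame(
        rows, columns=["day", "fBM", "D", "Sv", "E", "psi", "AOBL", "AOCL", "Df", "Dr"]
    )


def simulate(
    schedule: LoadingSchedule,
    initial: BoneState,
    params: ModelParameters | None = None,
    output_step: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate the coupled ODE over a loading schedule.

    Integration restarts at each segment boundary.  The run terminates at the
    first time damage reaches 1 (located by event detection); the final output
    sample is then the failure time itself.
    """
    params = params or ModelParameters()
    times = [0.0]
    fBM = [initial.fBM]
    D = [initial.D]
    loadings = [schedule.loading_at(0.0) if schedule.segments else
                LoadingCondition(sigma=0.0, strain_rate=1.0, vn=0.0)]
    failure_day: float | None = 0.0 if initial.D >= 1 else None
    clipped = False
    y = np.array([initial.fBM, initial.D], dtype=float)

    for start, end, loading in schedule.segments:
        if failure_day is not None:
            break
        sol = solve_ivp(
            _rhs_arrays, (start, end), y, args=(loading, params),
            method=method, rtol=rtol, atol=atol, dense_output=True,
            events=_failure_event,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed in segment [{start}, {end}] "
                f"from state {y}: {sol.message}"
            )
        seg_end = sol.t[-1]
        grid = np.arange(start + output_step, seg_end + 1e-12, output_step)
        grid = grid[grid <= seg_end + 1e-12]
        if grid.size == 0 or not math.isclose(grid[-1], seg_end, abs_tol=1e-9):
            grid = np.append(grid, seg_end)
        states = sol.sol(grid)
        if np.any(states[0] > 1.0) or np.any(states[0] <= 0.0):
            clipped = True
        states[0] = np.clip(states[0], _FBM_MIN, _FBM_MAX)
        times.extend(grid.tolist())
        fBM.extend(states[0].tolist())
        D.extend(states[1].tolist())
        loadings.extend([loading] * grid.size)
        y = sol.y[:, -1].copy()
        if sol.t_events[0].size > 0:
            failure_day = float(sol.t_events[0][0])
            D[-1] = 1.0
            break

    times_arr = np.asarray(times)
    fBM_arr = np.asarray(fBM)
    D_arr = np.asarray(D)
    trace = _bundle_rows(times_arr, fBM_arr, D_arr, loadings, params)
    return SimulationResult(
        times=times_arr, fBM=fBM_arr, D=D_arr, trace=trace,
        failure_day=failure_day,
        terminated_early=failure_day is not None
        and schedule.segments != ()
        and failure_day < schedule.total_duration - 1e-9,
        clipped=clipped,
    )


@dataclass
class SteadyStateResult:
    """Outcome of a steady-state search under constant loading."""

    state: BoneState                 # steady fBM and quasi-steady D (Df' = Dr')
    converged: bool
    boundary: bool                   # fBM ran into the fBM -> 1 boundary
    degenerate: bool = False         # AOBL == AOCL identically: any fBM is stationary
    time_to_steady: float | None = None   # first day the criterion window starts
    message: str = ""


def _quasi_steady_damage(fBM: float, loading: LoadingCondition,
                         params: ModelParameters) -> float:
    """Damage at which formation balances repair, at fixed fBM (can exceed 1)."""
    probe = BoneState(fBM=fBM, D=1.0)
    b = model_rhs(0.0, probe, loading, params)
    if b.Dr <= 0.0:
        return 0.0 if b.Df == 0.0 else math.inf
    return b.Df / b.Dr  # Dr is linear in D, evaluated here at D = 1


def steady_state(
    loading: LoadingCondition,
    params: ModelParameters | None = None,
    fBM_guess: float = 0.9,
    horizon: float = 20000.0,
    rate_tol: float = 1e-7,
    sustain: float = 50.0,
) -> SteadyStateResult:
    """Locate the steady state of fBM under constant loading.

    Integrates from ``fBM_guess`` until |dfBM/dt| stays below ``rate_tol``
    (1/day) for ``sustain`` consecutive days, and reports the first day that
    sustained window starts.  The quasi-steady damage solves Df' = Dr' at the
    steady fBM.  Boundary-type steady states (fBM -> 1, where the remodelling
    surface vanishes) are flagged.
    """
    params = params or ModelParameters()

    # Degenerate case: formation and resorption identical for every signal.
    probe_rates = [
        model_rhs(0.0, BoneState(fBM=f), loading, params).dfBM_dt
        for f in (0.05, 0.3, 0.5, 0.7, 0.95)
    ]
    if all(abs(r) < 1e-15 for r in probe_rates):
        D_qs = _quasi_steady_damage(fBM_guess, loading, params)
        return SteadyStateResult(
            state=BoneState(fBM=fBM_guess, D=min(D_qs, 1.0)),
            converged=True, boundary=False, degenerate=True,
            time_to_steady=0.0,
            message="AOBL == AOCL for all psi: every fBM is stationary",
        )

    sched = LoadingSchedule.constant(
        LoadingCondition(loading.sigma, loading.strain_rate, 0.0), horizon
    )
    res = simulate(sched, BoneState(fBM=fBM_guess, D=0.0), params, output_step=1.0)
    rates = np.array([
        model_rhs(t, BoneState(fBM=min(max(f, _FBM_MIN), _FBM_MAX)), loading, params).dfBM_dt
        for t, f in zip(res.times, res.fBM)
    ])
    below = np.abs(rates) < rate_tol
    window = int(round(sustain))
    start_idx: int | None = None
    run = 0
    for i, ok in enumerate(below):
        run = run + 1 if ok else 0
        if run >= window + 1:
            start_idx = i - window
            break
    fBM_final = float(res.fBM[start_idx] if start_idx is not None else res.fBM[-1])
    boundary = fBM_final > 1.0 - 1e-6
    D_qs = _quasi_steady_damage(fBM_final, loading, params)
    if start_idx is None:
        return SteadyStateResult(
            state=BoneState(fBM=fBM_final, D=min(D_qs, 1.0)),
            converged=False, boundary=boundary,
            message=f"criterion not met within {horizon} days; last state returned",
        )
    return SteadyStateResult(
        state=BoneState(fBM=fBM_final, D=min(D_qs, 1.0)),
        converged=True, boundary=boundary,
        time_to_steady=float(res.times[start_idx]),
    )


@dataclass
class TimeToFailureResult:
    """Time to D* = 1, or why it was not reached."""

    days: float | None
    status: str                 # "failed" | "plateau" | "horizon"
    final_state: BoneState

    def __bool__(self) -> bool:  # truthy iff failure occurred
        return self.days is not None


def time_to_failure(
    loading: LoadingCondition,
    initial: BoneState,
    params: ModelParameters | None = None,
    horizon: float = 2000.0,
    plateau_tol: float = 1e-3,
) -> TimeToFailureResult:
    """First day damage reaches 1 under constant loading.

    Returns a plateau outcome when dD*/dt falls below ``plateau_tol`` (1/day)
    with damage still below 1 (repair balancing formation), and a horizon
    outcome when the budget is exhausted while damage is still growing.  The
    default plateau threshold of 1e-3/day declares damage stationary when it
    would need over 1000 days — several racing campaigns — to traverse the
    unit interval, an order of magnitude below training-intensity formation
    rates.
    """
    params = params or ModelParameters()
    if initial.D >= 1.0:
        return TimeToFailureResult(days=0.0, status="failed", final_state=initial)
    if loading.vn == 0.0 and initial.D >= 0.0:
        # No cycles: damage can only decay; failure is impossible.
        return TimeToFailureResult(days=None, status="plateau", final_state=initial)

    chunk = 100.0
    y = BoneState(fBM=initial.fBM, D=initial.D)
    t = 0.0
    while t < horizon:
        t_end = min(t + chunk, horizon)
        sched = LoadingSchedule.constant(loading, t_end - t)
        res = simulate(sched, y, params, output_step=1.0)
        if res.failure_day is not None:
            return TimeToFailureResult(
                days=t + res.failure_day, status="failed", final_state=res.final_state
            )
        y = res.final_state
        dD = model_rhs(t_end, y, loading, params).dD_dt
        if abs(dD) < plateau_tol and y.D < 1.0:
            return TimeToFailureResult(days=None, status="plateau", final_state=y)
        t = t_end
    return TimeToFailureResult(days=None, status="horizon", final_state=y)
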