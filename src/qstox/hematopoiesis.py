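"""Transit-compartment model of chemotherapy-induced myelosuppression.

The model tracks a proliferating progenitor pool, ``n_transit`` maturation
compartments, and circulating mature cells (neutrophils).  Proliferation is
stimulated by a negative feedback from circulating cells,
``(circ0 / circ) ** gamma``; all first-order rate constants equal
``k = (n_transit + 1) / mtt``, so at homeostasis every compartment sits at the
circulating baseline ``circ0``.

Treatment is modelled as instantaneous fractional kill of the proliferating
pool only; the integrator stops and restarts at each dose time so the
trajectory is continuous everywhere else.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParams",
    "TreatmentSchedule",
    "Trajectory",
    "RecoverySummary",
    "DEFAULT_CTCAE_THRESHOLDS",
    "steady_state",
    "model_rhs",
    "simulate",
    "grade_neutropenia",
    "recovery_summary",
    "interdose_recovery",
    "local_maxima",
]

logger = logging.getLogger(__name__)

#: CTCAE-style neutropenia grade cut-offs, 10^9 cells/L, most lenient first.
#: A count at or below a cut-off receives at least that grade (ties go to the
#: more severe grade).
DEFAULT_CTCAE_THRESHOLDS: tuple[float, ...] = (1.5, 1.0, 0.5, 0.25)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the myelosuppression model.

    Parameters
    ----------
    circ0
        Baseline circulating cell concentration, 10^9 cells/L. Must be > 0.
    mtt
        Mean transit (maturation) time through the chain, hours. Must be > 0.
    gamma
        Feedback exponent coupling circulating cells to progenitor
        proliferation; dimensionless, >= 0. Controls the qualitative
        dynamics (see :mod:`qstox.stability`).
    n_transit
        Number of transit compartments in the maturation chain.
    """

    circ0: float = 5.05
    mtt: float = 125.0
    gamma: float = 0.17
    n_transit: int = 3

    def __post_init__(self) -> None:
        if not self.circ0 > 0:
            raise ValueError(f"circ0 must be > 0, got {self.circ0}")
        if not self.mtt > 0:
            raise ValueError(f"mtt must be > 0, got {self.mtt}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if not (isinstance(self.n_transit, (int, np.integer)) and self.n_transit >= 1):
            raise ValueError(f"n_transit must be a positive integer, got {self.n_transit}")

    @property
    def k(self) -> float:
        """Common first-order rate constant, per hour: (n_transit + 1) / mtt."""
        return (self.n_transit + 1) / self.mtt

    @property
    def n_states(self) -> int:
        return self.n_transit + 2

    @property
    def state_names(self) -> tuple[str, ...]:
        return ("prol", *(f"transit_{i}" for i in range(1, self.n_transit + 1)), "circ")

    def to_dict(self) -> dict:
        return {
            "circ0": self.circ0,
            "mtt": self.mtt,
            "gamma": self.gamma,
            "n_transit": self.n_transit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {"circ0", "mtt", "gamma", "n_transit"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown ModelParams fields: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class TreatmentSchedule:
    """Ordered instantaneous fractional-kill events on the proliferating pool.

    ``events`` is a sequence of ``(time_h, kill_fraction)`` pairs with strictly
    increasing times and fractions in [0, 1].
    """

    events: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        ev = tuple((float(t), float(f)) for t, f in self.events)
        object.__setattr__(self, "events", ev)
        times = [t for t, _ in ev]
        if any(t < 0 for t in times):
            raise ValueError("event times must be >= 0")
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if any(not (0.0 <= f <= 1.0) for _, f in ev):
            raise ValueError("kill fractions must lie in [0, 1]")

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.events)

    @property
    def last_time(self) -> float:
        return self.events[-1][0] if self.events else 0.0

    @classmethod
    def single_dose(cls, kill_fraction: float, time: float = 0.0) -> "TreatmentSchedule":
        return cls(((time, kill_fraction),))

    @classmethod
    def repeated(
        cls, kill_fraction: float, interval: float, n_doses: int, start: float = 0.0
    ) -> "TreatmentSchedule":
        if n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        return cls(tuple((start + i * interval, kill_fraction) for i in range(n_doses)))

    def to_json(self, path) -> None:
        payload = {"events": [{"time_h": t, "kill_fraction": f} for t, f in self.events]}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TreatmentSchedule":
        with open(path) as fh:
            payload = json.load(fh)
        try:
            events = tuple((e["time_h"], e["kill_fraction"]) for e in payload["events"])
        except (KeyError, TypeError) as exc:
            raise ValueError(f"malformed schedule file {path}: {exc}") from exc
        return cls(events)


@dataclass(frozen=True)
class Trajectory:
    """Time-gridded solution of the model.

    ``states`` has one row per time point, columns ordered
    ``prol, transit_1..transit_n, circ``.
    """

    times: np.ndarray
    states: np.ndarray
    params: ModelParams
    schedule: TreatmentSchedule = field(default_factory=TreatmentSchedule)

    @property
    def prol(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def circ(self) -> np.ndarray:
        return self.states[:, -1]

    def grades(self, thresholds: Sequence[float] = DEFAULT_CTCAE_THRESHOLDS) -> np.ndarray:
        return grade_neutropenia(self.circ, thresholds)

    def to_frame(self, include_grades: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.params.state_names)
        df.insert(0, "time_h", self.times)
        if include_grades:
            df["neutropenia_grade"] = self.grades()
        return df

    def to_csv(self, path, include_grades: bool = False) -> None:
        self.to_frame(include_grades=include_grades).to_csv(path, index=False)


def steady_state(params: ModelParams) -> np.ndarray:
    """Homeostatic equilibrium: every compartment equals ``circ0``.

    With all rate constants equal, flux balance along the chain forces equal
    levels, and the feedback term equals one, so the derivative vanishes.
    """
    return np.full(params.n_states, params.circ0, dtype=float)


def model_rhs(state: np.ndarray, params: ModelParams, _floor_log: list | None = None) -> np.ndarray:
    """Instantaneous derivatives of (prol, transit_1..n, circ).

    The circulating concentration is floored at ``1e-12 * circ0`` inside the
    feedback term only; activations are logged (and appended to ``_floor_log``
    when given).
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (params.n_states,):
        raise ValueError(f"state must have shape ({params.n_states},), got {state.shape}")
    k = params.k
    prol = state[0]
    circ = state[-1]
    floor = 1e-12 * params.circ0
    if circ < floor:
        if _floor_log is not None:
            _floor_log.append(float(circ))
        logger.warning("feedback floor activated: circ=%.3e < %.3e", circ, floor)
        circ_fb = floor
    else:
        circ_fb = circ
    feedback = (params.circ0 / circ_fb) ** params.gamma
    d = np.empty_like(state)
    d[0] = k * prol * feedback - k * prol
    d[1] = k * (prol - state[1])
    for i in range(2, params.n_transit + 1):
        d[i] = k * (state[i - 1] - state[i])
    d[-1] = k * (state[-2] - state[-1])
    return d


def simulate(
    params: ModelParams,
    schedule: TreatmentSchedule | None = None,
    horizon: float = 2160.0,
    output_step: float = 1.0,
    initial_state: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the model over ``[0, horizon]`` under a treatment schedule.

    Each event instantaneously multiplies the proliferating pool by
    ``1 - kill_fraction``; integration stops and restarts at event times.  At
    an event grid point the recorded state is the post-dose state.
    """
    schedule = schedule or TreatmentSchedule()
    if schedule.events and horizon <= schedule.last_time:
        raise ValueError(
            f"horizon ({horizon} h) must exceed the last event time ({schedule.last_time} h)"
        )
    if output_step <= 0:
        raise ValueError("output_step must be > 0")

    y = np.array(steady_state(params) if initial_state is None else initial_state, dtype=float)
    if y.shape != (params.n_states,):
        raise ValueError(f"initial_state must have shape ({params.n_states},)")

    grid = np.arange(0.0, horizon + output_step * 0.5, output_step)
    out = np.empty((grid.size, params.n_states))
    floor_log: list[float] = []

    def rhs(t, state):
        return model_rhs(state, params, _floor_log=floor_log)

    # breakpoints: 0, event times, horizon
    breaks = [0.0] + [t for t in schedule.times if 0.0 < t < horizon] + [horizon]
    events = dict(schedule.events)

    # dose at t = 0 applies to the initial condition
    if schedule.events and schedule.events[0][0] == 0.0:
        y[0] *= 1.0 - events[0.0]

    filled = 0
    if grid[0] == 0.0:
        out[0] = y
        filled = 1

    for t0, t1 in zip(breaks, breaks[1:]):
        sol = solve_ivp(
            rhs, (t0, t1), y, method="LSODA", rtol=rtol, atol=atol, dense_output=True
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed on [{t0}, {t1}] h: {sol.message}"
            )
        # fill grid points in (t0, t1]; the point at t1 itself is overwritten
        # post-dose below if t1 is an event time
        hi = np.searchsorted(grid, t1, side="right")
        seg = grid[filled:hi]
        if seg.size:
            out[filled:hi] = sol.sol(seg).T
        filled = hi
        y = sol.y[:, -1]
        if t1 in events:
            y[0] *= 1.0 - events[t1]
            if filled and grid[filled - 1] == t1:
                out[filled - 1] = y

    neg = out < 0
    if neg.any():
        worst = out[neg].min()
        logger.warning("clamping %d negative state values (min %.3e)", int(neg.sum()), worst)
        out = np.where(neg, 0.0, out)
    if floor_log:
        logger.warning("feedback floor activated %d times during integration", len(floor_log))
    return Trajectory(times=grid, states=out, params=params, schedule=schedule)


def grade_neutropenia(
    circ_value, thresholds: Sequence[float] = DEFAULT_CTCAE_THRESHOLDS
):
    """Map circulating neutrophil concentration to CTCAE-style grade 0-4.

    A value at or below a cut-off takes the more severe grade. Accepts scalars
    or arrays; rejects negative input.
    """
    thresholds = tuple(thresholds)
    if any(t1 <= t2 for t1, t2 in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly decreasing")
    arr = np.asarray(circ_value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("circulating concentration must be >= 0")
    grade = np.zeros(arr.shape, dtype=int)
    for t in thresholds:
        grade += arr <= t
    if np.isscalar(circ_value) or arr.ndim == 0:
        return int(grade)
    return grade


@dataclass(frozen=True)
class RecoverySummary:
    nadir_value: float
    nadir_time: float
    recovery_time: float | None  # None: no sustained return within the horizon
    recovered: bool
    first_in_band_time: float | None = None  # first return into the band

    def to_dict(self) -> dict:
        return {
            "nadir_value": self.nadir_value,
            "nadir_time_h": self.nadir_time,
            "recovery_time_h": self.recovery_time,
            "recovered": self.recovered,
            "first_in_band_time_h": self.first_in_band_time,
        }


def recovery_summary(traj: Trajectory, tolerance_fraction: float = 0.02) -> RecoverySummary:
    """Nadir and recovery metrics of the circulating compartment.

    Two complementary recovery notions are reported relative to the band
    ``|circ - circ0| <= tolerance_fraction * circ0``:

    * ``recovery_time`` — sustained recovery: the first time after the last
      dose from which the count remains inside the band for the rest of the
      simulated horizon.  Near the oscillatory regime the slowly damped
      rebound oscillations dominate this time.  None if the trajectory is
      still outside the band at the final grid point.
    * ``first_in_band_time`` — first re-entry into the band after leaving it
      (the time at which the count first climbs back to baseline, before any
      rebound overshoot).  None if the band is never re-entered.
    """
    circ = traj.circ
    c0 = traj.params.circ0
    if not traj.schedule.events:
        i = int(np.argmin(circ))
        return RecoverySummary(float(circ[i]), float(traj.times[i]), 0.0, True, 0.0)

    after = traj.times >= traj.schedule.last_time
    circ_a = circ[after]
    times_a = traj.times[after]
    i = int(np.argmin(circ_a))
    nadir_value, nadir_time = float(circ_a[i]), float(times_a[i])

    outside = np.abs(circ_a - c0) > tolerance_fraction * c0
    first_in_band: float | None
    if not outside.any():
        first_in_band = float(times_a[0])
    else:
        first_out = int(np.argmax(outside))
        back = np.nonzero(~outside[first_out:])[0]
        first_in_band = float(times_a[first_out + back[0]]) if back.size else None

    if outside[-1]:
        return RecoverySummary(nadir_value, nadir_time, None, False, first_in_band)
    if not outside.any():
        return RecoverySummary(nadir_value, nadir_time, float(times_a[0]), True, first_in_band)
    last_violation = int(np.max(np.nonzero(outside)[0]))
    return RecoverySummary(
        nadir_value, nadir_time, float(times_a[last_violation + 1]), True, first_in_band
    )


def interdose_recovery(
    traj: Trajectory,
    tolerance_fraction: float = 0.02,
    min_hold_h: float = 24.0,
) -> list[bool]:
    """Whether the count returns to baseline between consecutive doses.

    For each inter-dose interval (and the tail after the last dose), True if
    the circulating count spends at least ``min_hold_h`` contiguous hours
    inside the band ``|circ - circ0| <= tolerance_fraction * circ0``.  A mere
    grid-point graze of the band does not count as a return to homeostasis.
    """
    if len(traj.schedule.events) < 1:
        raise ValueError("schedule has no events")
    c0 = traj.params.circ0
    in_band = np.abs(traj.circ - c0) <= tolerance_fraction * c0
    bounds = list(traj.schedule.times) + [float(traj.times[-1])]
    results = []
    for lo, hi in zip(bounds, bounds[1:]):
        seg = (traj.times >= lo) & (traj.times <= hi)
        t_seg, b_seg = traj.times[seg], in_band[seg]
        held = False
        run_start = None
        for t, b in zip(t_seg, b_seg):
            if b:
                if run_start is None:
                    run_start = t
                if t - run_start >= min_hold_h:
                    held = True
                    break
            else:
                run_start = None
        results.append(held)
    return results


def local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima (greater than both grid neighbours)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        return np.array([], dtype=int)
    return np.nonzero((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:]))[0] + 1
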