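"""Integration of the delayed circuit model.

The system is advanced by the *method of steps*: on successive intervals no
longer than the shortest positive delay, the delayed terms fall entirely in
already-computed history, so each interval is an ordinary (non-delayed) IVP
handed to :func:`scipy.integrate.solve_ivp`.  The stored dense outputs of
earlier intervals serve as the history interpolant (the approach of the
classic ``dde23`` solver).  History before t = 0 is the constant
pre-induction steady state.

A deliberately naive fixed-step Euler integrator with ring-buffer delayed
lookups (:func:`euler_oracle`) is provided for verification only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    AUX_STATES,
    N_SPECIES,
    N_STATE,
    SPECIES,
    CircuitError,
    CircuitParameters,
    CircuitState,
    FeedbackVariant,
    InductionSchedule,
    observables,
    rhs,
)

__all__ = [
    "SolverSettings",
    "Trajectory",
    "SteadyStateError",
    "IntegrationError",
    "find_preinduction_steady_state",
    "simulate",
    "euler_oracle",
]

_NEG_TOL = 1e-9  # components in [-1e-9, 0] clamp to zero; worse is an error


class SteadyStateError(RuntimeError):
    """Pre-induction burn-in failed to stagnate within its time budget."""


class IntegrationError(RuntimeError):
    """The solver failed on some interval of the method of steps."""


@dataclass(frozen=True)
class SolverSettings:
    """Numerical knobs for the DDE integration.

    ``history_interp`` selects how delayed lookups read past solution
    segments: ``"cubic"`` uses the solver's dense output, ``"linear"``
    interpolates linearly between accepted steps.  ``steady_state_tol`` is
    the largest |derivative| (concentration/h) accepted as stationary;
    ``oracle_dt`` is the default step of the Euler verification integrator.
    """

    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    max_step: float = math.inf
    history_interp: str = "cubic"
    steady_state_tol: float = 1e-7
    oracle_dt: float = 1e-4
    burn_in_factor: float = 50.0  # burn-in horizon = burn_in_factor / mu0
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise CircuitError("tolerances must be positive")
        if self.history_interp not in ("linear", "cubic"):
            raise CircuitError("history_interp must be 'linear' or 'cubic'")


@dataclass
class Trajectory:
    """Solution of one simulation: times, full state matrix and metadata.

    ``states`` has one row per time and ``N_STATE`` columns (8 species plus
    3 cumulative GFP-flux accumulators).  ``at(t)`` evaluates the underlying
    history interpolant at arbitrary times in [0, t_end].
    """

    times: np.ndarray
    states: np.ndarray
    params: CircuitParameters
    variant: FeedbackVariant
    schedule: InductionSchedule
    settings_used: SolverSettings
    events: list = field(default_factory=list)
    _history: "_History | None" = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise CircuitError("trajectory times must be strictly increasing")

    def at(self, t) -> np.ndarray:
        """State vector(s) at arbitrary time(s) within the horizon."""
        tq = np.atleast_1d(np.asarray(t, dtype=float))
        if self._history is not None:
            out = np.stack([self._history.lookup(ti) for ti in tq])
        else:
            out = np.stack(
                [np.interp(tq, self.times, self.states[:, j]) for j in range(self.states.shape[1])],
                axis=1,
            )
        out[:, :N_SPECIES] = np.maximum(out[:, :N_SPECIES], 0.0)
        return out[0] if np.ndim(t) == 0 else out

    def state_at(self, t: float) -> CircuitState:
        return CircuitState.from_vector(self.at(float(t)))

    def observable(self, name: str, t) -> np.ndarray | float:
        """A derived observable (``total_gfp`` etc.) at time(s) ``t``."""
        ys = self.at(t)
        if np.ndim(t) == 0:
            return observables(ys, self.params)[name]
        return np.array([observables(y, self.params)[name] for y in ys])

    @property
    def endpoint(self) -> CircuitState:
        return CircuitState.from_vector(self.states[-1])

    def to_frame(self, run_id: str = "run0") -> pd.DataFrame:
        """Tidy long-format export: time, species, value, variant, run_id."""
        cols = SPECIES + AUX_STATES
        wide = pd.DataFrame(self.states, columns=cols)
        wide.insert(0, "time_h", self.times)
        long = wide.melt(id_vars="time_h", var_name="species", value_name="value")
        long["variant"] = self.variant.label
        long["run_id"] = run_id
        return long

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["time_h", "event"])


class _History:
    """Piecewise solution history with constant pre-t=0 state."""

    def __init__(self, y0: np.ndarray, interp: str):
        self.y0 = np.asarray(y0, dtype=float)
        self.interp = interp
        self.seg_bounds: list[tuple[float, float]] = []
        self.seg_dense: list = []  # OdeSolution per segment (cubic mode)
        self.node_t: list[float] = [0.0]
        self.node_y: list[np.ndarray] = [self.y0]

    def add_segment(self, t0: float, t1: float, sol) -> None:
        self.seg_bounds.append((t0, t1))
        self.seg_dense.append(sol.sol)
        self.node_t.extend(sol.t[1:].tolist())
        self.node_y.extend(list(sol.y.T[1:]))

    @property
    def t_end(self) -> float:
        return self.seg_bounds[-1][1] if self.seg_bounds else 0.0

    def lookup(self, t: float) -> np.ndarray:
        if t <= 0.0:
            return self.y0
        if self.interp == "linear":
            ts = np.asarray(self.node_t)
            i = np.searchsorted(ts, t, side="right")
            i = min(max(i, 1), len(ts) - 1)
            t0, t1 = ts[i - 1], ts[i]
            y0, y1 = self.node_y[i - 1], self.node_y[i]
            if t >= ts[-1]:
                return self.node_y[-1]
            w = (t - t0) / (t1 - t0)
            return (1 - w) * y0 + w * y1
        # cubic: locate the segment dense output covering t
        for (a, b), dense in zip(reversed(self.seg_bounds), reversed(self.seg_dense)):
            if a - 1e-12 <= t <= b + 1e-12:
                return dense(min(max(t, a), b))
        raise CircuitError(f"history lookup outside stored range: t={t}")


def _preinduction_params(schedule: InductionSchedule) -> InductionSchedule:
    return InductionSchedule(iptg_conc=0.0, t_induce=0.0, t_end=schedule.t_end)


def find_preinduction_steady_state(
    params: CircuitParameters,
    settings: SolverSettings = SolverSettings(),
) -> CircuitState:
    """Steady state of the un-induced circuit, used as t<=0 history.

    Constant solutions of the delayed system satisfy the same balance as the
    delay-free system, so the burn-in integrates the plain ODE from an empty
    cell in chunks until every species' |derivative| falls below
    ``steady_state_tol`` (stagnation test), within a horizon of
    ``burn_in_factor / mu0`` hours.  Non-convergence raises
    :class:`SteadyStateError` naming the slowest species.
    """
    sched0 = InductionSchedule(iptg_conc=0.0, t_induce=0.0, t_end=1.0)
    y = np.zeros(N_STATE)

    def f(t, yv):
        yc = yv.copy()
        yc[:N_SPECIES] = np.maximum(yc[:N_SPECIES], 0.0)
        return rhs(t, yc, lambda tq: yc, params, sched0)

    # time scale: burn-in budget relative to dilution; mu0=0 gets a fixed budget
    total = settings.burn_in_factor / params.mu0 if params.mu0 > 0 else 500.0
    chunk = total / 10.0
    t = 0.0
    while t < total * (1 + 1e-9):
        sol = solve_ivp(
            f,
            (t, t + chunk),
            y,
            method=settings.method,
            rtol=settings.rel_tol,
            atol=settings.abs_tol,
        )
        if not sol.success:
            raise SteadyStateError(f"burn-in integration failed: {sol.message}")
        y = sol.y[:, -1]
        t += chunk
        dy = f(t, y)[:N_SPECIES]
        if np.max(np.abs(dy)) < settings.steady_state_tol:
            y = np.maximum(y, 0.0)
            y[N_SPECIES:] = 0.0
            return CircuitState.from_vector(y)
    slowest = SPECIES[int(np.argmax(np.abs(dy)))]
    raise SteadyStateError(
        f"pre-induction burn-in did not reach steady state within {total:.1f} h; "
        f"slowest species: {slowest} (|d/dt| = {np.max(np.abs(dy)):.3g})"
    )


def _segment_grid(schedule: InductionSchedule, params: CircuitParameters) -> np.ndarray:
    """Breakpoints for the method of steps: min positive delay, plus t_induce."""
    delays = [d for d in (params.tau_tx, params.tau_tl) if d > 0]
    pts = {0.0, schedule.t_end, min(schedule.t_induce, schedule.t_end)}
    if delays:
        step = min(delays)
        pts.update(np.arange(step, schedule.t_end, step).tolist())
        # propagated discontinuity of the induction step
        for shift in (params.tau_tx, params.tau_tx + params.tau_tl):
            ti = schedule.t_induce + shift
            if ti < schedule.t_end:
                pts.add(ti)
    grid = np.array(sorted(pts))
    return grid[np.concatenate(([True], np.diff(grid) > 1e-12))]


def simulate(
    params: CircuitParameters,
    variant: FeedbackVariant,
    schedule: InductionSchedule,
    settings: SolverSettings = SolverSettings(),
) -> Trajectory:
    """Integrate the circuit over ``[0, t_end]`` with induction at ``t_induce``.

    The variant's promoter/RBS scales are applied to ``params`` first; the
    initial condition and the t<=0 history are the pre-induction steady
    state.  With both delays zero the method of steps degenerates to plain
    stepping over the pieces of the induction schedule.
    """
    p = variant.apply(params)
    ss = find_preinduction_steady_state(p, settings)
    y0 = ss.to_vector()
    hist = _History(y0, settings.history_interp)
    grid = _segment_grid(schedule, p)

    y = y0.copy()
    for a, b in zip(grid[:-1], grid[1:]):

        def f(t, yv, _a=a):
            yc = yv.copy()
            yc[:N_SPECIES] = np.maximum(yc[:N_SPECIES], 0.0)

            def delayed(tq):
                if tq >= t - 1e-12:
                    return yc
                return hist.lookup(tq)

            return rhs(t, yc, delayed, p, schedule)

        sol = solve_ivp(
            f,
            (a, b),
            y,
            method=settings.method,
            dense_output=True,
            rtol=settings.rel_tol,
            atol=settings.abs_tol,
            max_step=settings.max_step,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed on interval [{a:.4f}, {b:.4f}] h: {sol.message}"
            )
        worst = sol.y[:N_SPECIES].min()
        if worst < -_NEG_TOL:
            raise IntegrationError(
                f"negative concentration ({worst:.3g}) on interval [{a:.4f}, {b:.4f}] h"
            )
        hist.add_segment(a, b, sol)
        y = sol.y[:, -1].copy()
        y[:N_SPECIES] = np.maximum(y[:N_SPECIES], 0.0)

    times = np.array(sorted(set(np.round(hist.node_t, 12))))
    states = np.stack([hist.lookup(t) for t in times])
    states[:, :N_SPECIES] = np.maximum(states[:, :N_SPECIES], 0.0)
    events = []
    if schedule.t_induce <= schedule.t_end:
        events.append((schedule.t_induce, f"induction iptg={schedule.iptg_conc} mM"))
    return Trajectory(
        times=times,
        states=states,
        params=p,
        variant=variant,
        schedule=schedule,
        settings_used=settings,
        events=events,
        _history=hist,
    )


def euler_oracle(
    params: CircuitParameters,
    variant: FeedbackVariant,
    schedule: InductionSchedule,
    dt: float | None = None,
    settings: SolverSettings = SolverSettings(),
) -> Trajectory:
    """Brute-force fixed-step explicit Euler DDE integration (tests only).

    Delayed lookups read a ring buffer of past states at integer step
    offsets, so ``dt`` (default ``settings.oracle_dt``) must not exceed the
    shortest positive delay (and the delays are rounded to whole steps).
    First-order accurate; exists purely as an independent cross-check of
    :func:`simulate`.
    """
    if dt is None:
        dt = settings.oracle_dt
    delays = [d for d in (params.tau_tx, params.tau_tl) if d > 0]
    if delays and dt > min(delays) + 1e-15:
        raise CircuitError(f"oracle dt={dt} exceeds the shortest delay {min(delays)}")
    p = variant.apply(params)
    ss = find_preinduction_steady_state(p, settings)
    y0 = ss.to_vector()

    n = int(round(schedule.t_end / dt))
    Y = np.empty((n + 1, N_STATE))
    Y[0] = y0
    k_tx = int(round(p.tau_tx / dt))
    k_tl = int(round(p.tau_tl / dt))

    def delayed_at(i: int) -> np.ndarray:
        return Y[i] if i >= 0 else y0

    for i in range(n):
        t = i * dt
        yi = Y[i]

        def delayed(tq, _i=i, _t=t, _yi=yi):
            k = _i - int(round((_t - tq) / dt))
            return delayed_at(k)

        Y[i + 1] = yi + dt * rhs(t, yi, delayed, p, schedule)
        np.maximum(Y[i + 1, :N_SPECIES], 0.0, out=Y[i + 1, :N_SPECIES])

    times = np.arange(n + 1) * dt
    return Trajectory(
        times=times,
        states=Y,
        params=p,
        variant=variant,
        schedule=schedule,
        settings_used=replace(settings, oracle_dt=dt),
        events=[(schedule.t_induce, f"induction iptg={schedule.iptg_conc} mM")],
    )
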