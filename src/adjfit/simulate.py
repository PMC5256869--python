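"""Forward simulation of compiled ODE models with state-jump events.

Integration stops exactly at every event time, applies the jump assignment
and restarts, so measurement and event times are always on the solver grid
(never interpolated across a discontinuity).  Each inter-event interval
keeps its dense-output interpolant so the backward adjoint solve can
evaluate x(t) anywhere without re-integration or checkpointing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import CompiledModel

__all__ = ["SolverSettings", "Trajectory", "SimulationError", "simulate"]


class SimulationError(RuntimeError):
    """Integration failure; carries the time at which it occurred."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


@dataclass(frozen=True)
class SolverSettings:
    """Tolerances and method for the stiff/non-stiff integrator.

    Defaults are rtol 1e-8 / atol 1e-16; ``method`` is any solve_ivp method
    name ("LSODA" switches between stiff and non-stiff automatically, "BDF"
    forces the stiff path).  ``max_step`` caps the internal step size.
    """

    rtol: float = 1e-8
    atol: float = 1e-16
    method: str = "LSODA"
    max_step: float = np.inf
    use_jacobian: bool = True
    #: terminal guard: integration aborts with a divergence error once any
    #: state magnitude crosses this bound (finite-time blow-up protection)
    divergence_threshold: float = 1e12

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class Segment:
    """Dense solution on one inter-event interval [t_lo, t_hi]."""

    t_lo: float
    t_hi: float
    interpolant: object  # scipy OdeSolution over the segment

    def state(self, t: float | np.ndarray) -> np.ndarray:
        return np.asarray(self.interpolant(t), dtype=float)


@dataclass
class Trajectory:
    """Solution of the initial value problem at the measurement times.

    ``states``/``outputs`` are time-major: shape (N, n_x) and (N, n_y).
    If a measurement time coincides with an event time, the stored state is
    the post-event state (a measurement observes the system after the jump);
    the pre-event value is kept in ``event_records``.
    """

    times: np.ndarray
    states: np.ndarray
    outputs: np.ndarray
    theta: np.ndarray
    segments: list[Segment]
    event_records: list[tuple[float, np.ndarray, np.ndarray]]  # (t_e, x_pre, x_post)
    solver_stats: dict = field(default_factory=dict)

    @property
    def t0(self) -> float:
        return self.segments[0].t_lo

    @property
    def t_end(self) -> float:
        return self.segments[-1].t_hi

    def segment_containing(self, t_lo: float, t_hi: float) -> Segment:
        """Segment covering [t_lo, t_hi]; the interval must not straddle an event."""
        for seg in self.segments:
            if seg.t_lo - 1e-12 <= t_lo and t_hi <= seg.t_hi + 1e-12:
                return seg
        raise SimulationError(
            f"no dense segment covers [{t_lo}, {t_hi}]", time=t_lo
        )

    def state(self, t: float) -> np.ndarray:
        """Dense-output state at time t (post-event side at event times)."""
        for seg in reversed(self.segments):
            if seg.t_lo - 1e-12 <= t <= seg.t_hi + 1e-12:
                return seg.state(t)
        raise SimulationError(f"time {t} outside trajectory range", time=t)


def divergence_guard(settings: SolverSettings):
    """Terminal solve_ivp event firing when the state leaves the finite
    range; prevents the integrator from grinding into a blow-up."""
    bound = settings.divergence_threshold

    def guard(t, z):
        m = np.max(np.abs(z))
        if not np.isfinite(m):
            return -1.0
        return bound - m

    guard.terminal = True
    return guard


def _integrate_segment(cm, theta, x_start, t_lo, t_hi, settings):
    if t_hi == t_lo:
        raise SimulationError("degenerate segment", time=t_lo)
    jac = None
    if settings.use_jacobian and settings.method in ("LSODA", "BDF", "Radau"):
        jac = lambda t, x: cm.J_x(x, theta)  # noqa: E731
    try:
        sol = solve_ivp(
            lambda t, x: cm.f(x, theta),
            (t_lo, t_hi),
            x_start,
            method=settings.method,
            dense_output=True,
            rtol=settings.rtol,
            atol=settings.atol,
            max_step=settings.max_step,
            jac=jac,
            events=divergence_guard(settings),
        )
    except (ValueError, OverflowError) as exc:
        # e.g. step-size collapse producing a degenerate dense grid
        raise SimulationError(f"solver failed on [{t_lo}, {t_hi}]: {exc}",
                              time=t_lo) from exc
    if sol.status == 1:  # divergence guard fired
        raise SimulationError(
            f"state diverged (|x| > {settings.divergence_threshold:g})",
            time=float(sol.t[-1]),
        )
    if not sol.success:
        raise SimulationError(
            f"solver failed on [{t_lo}, {t_hi}]: {sol.message}", time=sol.t[-1]
        )
    x_end = sol.y[:, -1]
    if not np.all(np.isfinite(x_end)):
        raise SimulationError("state diverged (NaN/Inf)", time=t_hi)
    return sol, x_end


def simulate(
    cm: CompiledModel,
    theta: Sequence[float],
    times: Sequence[float],
    settings: SolverSettings | None = None,
) -> Trajectory:
    """Solve the IVP for parameter vector ``theta`` and return states and
    outputs at the requested measurement ``times``.

    ``times`` must be sorted and >= t0.  Events strictly after the last
    measurement time are ignored.
    """
    settings = settings or SolverSettings()
    theta = np.asarray(theta, dtype=float)
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(times) < 0):
        raise ValueError("measurement times must be sorted ascending")
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    t0 = cm.t0
    if times[0] < t0:
        raise ValueError(f"measurement time {times[0]} precedes t0={t0}")
    t_end = float(times[-1])

    x = cm.x0(theta)
    if not np.all(np.isfinite(x)):
        raise SimulationError("initial state is not finite", time=t0)

    event_list = [ev for ev in cm.events if t0 < ev.time <= t_end]
    breakpoints = [t0] + [ev.time for ev in event_list] + [t_end]

    segments: list[Segment] = []
    event_records: list[tuple[float, np.ndarray, np.ndarray]] = []
    stats = {"n_steps": 0, "nfev": 0, "njev": 0, "n_solves": 1}

    n_t = times.size
    states = np.empty((n_t, cm.n_x))
    # measurements exactly at t0 (or at an event time) take the current
    # post-jump state directly
    filled = np.zeros(n_t, dtype=bool)
    at_start = np.isclose(times, t0)
    states[at_start] = x
    filled |= at_start

    for i_seg, (t_lo, t_hi) in enumerate(zip(breakpoints[:-1], breakpoints[1:])):
        if t_hi > t_lo:
            sol, x = _integrate_segment(cm, theta, x, t_lo, t_hi, settings)
            segments.append(Segment(t_lo, t_hi, sol.sol))
            stats["n_steps"] += sol.t.size - 1
            stats["nfev"] += sol.nfev
            stats["njev"] += getattr(sol, "njev", 0) or 0
            inside = (~filled) & (times > t_lo) & (times < t_hi)
            if np.any(inside):
                states[inside] = sol.sol(times[inside]).T
                filled |= inside
        # t_hi is an event time (all breakpoints except the last)
        if i_seg < len(event_list):
            ev = event_list[i_seg]
            x_pre = x.copy()
            x = ev.g(x_pre, theta)
            if not np.all(np.isfinite(x)):
                raise SimulationError("event assignment produced NaN/Inf", time=ev.time)
            event_records.append((ev.time, x_pre, x))
        # measurements exactly at t_hi observe the (post-event) state
        at_hi = (~filled) & np.isclose(times, t_hi)
        states[at_hi] = x
        filled |= at_hi

    if not np.all(filled):  # pragma: no cover - internal consistency
        raise SimulationError("internal error: unfilled measurement times")
    if not segments:
        # all measurement times equal t0: keep a trivial constant segment
        sol, _ = _integrate_segment(
            cm, theta, x, t0, t0 + max(1e-8, abs(t0) * 1e-8), settings
        )
        segments.append(Segment(t0, sol.t[-1], sol.sol))

    outputs = np.empty((n_t, cm.n_y))
    for j in range(n_t):
        outputs[j] = cm.h(states[j], theta)

    return Trajectory(
        times=times.copy(),
        states=states,
        outputs=outputs,
        theta=theta.copy(),
        segments=segments,
        event_records=event_records,
        solver_stats=stats,
    )
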