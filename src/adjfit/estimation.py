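"""Multi-start maximum-likelihood estimation with gradient-based local
optimization.

Start points come from a latin hypercube design over the parameter box
(on the log10 scale by default — kinetic constants span decades).  Each
start runs a bound-constrained local optimizer fed by one of the three
gradient engines:

* ``trust-region`` — scipy's trust-region-reflective least-squares on the
  weighted residual vector, with the residual Jacobian from forward
  sensitivities (the Gauss-Newton/FIM route).  Requires output
  sensitivities and therefore the forward engine.
* ``bfgs`` — L-BFGS-B on (J, grad) from any engine; the natural partner
  of the adjoint method, which yields the gradient but no per-observable
  sensitivities for a FIM.

Gradient failures at a start are flagged and the run recorded as failed,
never silently dropped; the multi-start result is sorted ascending by
final objective, ready for a waterfall plot.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize
from scipy.stats import qmc

from .gradients import FdScheme, forward_sensitivities, gradient
from .likelihood import ExperimentData, negloglik, residual_weights
from .model import CompiledModel
from .simulate import SimulationError, SolverSettings, simulate

__all__ = [
    "EstimationProblem",
    "StartResult",
    "MultiStartResult",
    "sample_starts",
    "optimize_local",
    "multistart",
    "waterfall",
]


@dataclass(frozen=True)
class EstimationProblem:
    """A bound-constrained ML estimation problem.

    Bounds are always given on the linear parameter scale; with
    ``scale="log10"`` (default) the optimizer works in log10 space and
    gradients are chain-ruled accordingly.  ``optimizer`` may be
    ``"auto"`` (trust-region when the gradient method is forward, BFGS
    otherwise), ``"trust-region"`` or ``"bfgs"``.
    """

    cm: CompiledModel
    data: ExperimentData
    lower: np.ndarray
    upper: np.ndarray
    scale: str = "log10"
    grad_method: str = "adjoint"
    optimizer: str = "auto"
    solver_settings: SolverSettings = field(default_factory=SolverSettings)
    fd_scheme: FdScheme = field(default_factory=FdScheme.central)
    max_iter: int = 200
    max_time_s: float = np.inf

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != (self.cm.n_theta,) or upper.shape != (self.cm.n_theta,):
            raise ValueError("bounds must have one entry per parameter")
        if not np.all(np.isfinite(lower)) or not np.all(np.isfinite(upper)):
            raise ValueError("bounds must be finite")
        if np.any(lower >= upper):
            raise ValueError("need lower < upper per dimension")
        if self.scale not in ("linear", "log10"):
            raise ValueError("scale must be 'linear' or 'log10'")
        if self.scale == "log10" and np.any(lower <= 0):
            raise ValueError("log10 scale requires strictly positive lower bounds")
        if self.grad_method not in ("fd", "forward", "adjoint"):
            raise ValueError(f"unknown gradient method {self.grad_method!r}")
        if self.optimizer not in ("auto", "trust-region", "bfgs"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

    @property
    def resolved_optimizer(self) -> str:
        if self.optimizer != "auto":
            if self.optimizer == "trust-region" and self.grad_method != "forward":
                raise ValueError(
                    "trust-region (FIM) optimization needs output sensitivities "
                    "and therefore grad_method='forward'"
                )
            return self.optimizer
        return "trust-region" if self.grad_method == "forward" else "bfgs"

    # -- scale transforms ---------------------------------------------------
    def to_internal(self, theta: np.ndarray) -> np.ndarray:
        return np.log10(theta) if self.scale == "log10" else np.asarray(theta, float)

    def to_linear(self, z: np.ndarray) -> np.ndarray:
        return 10.0 ** z if self.scale == "log10" else np.asarray(z, float)

    def grad_to_internal(self, grad_lin: np.ndarray, theta: np.ndarray) -> np.ndarray:
        if self.scale == "log10":
            return grad_lin * theta * np.log(10.0)
        return grad_lin


@dataclass
class StartResult:
    """Outcome of one local optimization run."""

    start: np.ndarray
    theta: np.ndarray
    J: float
    iterations: int
    converged: str  # "converged" | "budget" | "gradient-failure"
    trace: list[tuple[int, float, int]] = field(default_factory=list)
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.converged in ("converged", "budget")


@dataclass
class MultiStartResult:
    """All start results sorted ascending by final J (failures last)."""

    starts: list[StartResult]
    seed: int
    settings: dict = field(default_factory=dict)

    @property
    def best(self) -> StartResult:
        ok = [s for s in self.starts if s.ok]
        if not ok:
            raise RuntimeError("all optimization starts failed")
        return ok[0]

    @property
    def n_failed(self) -> int:
        return sum(1 for s in self.starts if not s.ok)


def sample_starts(
    lower: Sequence[float],
    upper: Sequence[float],
    n: int,
    seed: int,
    scale: str = "log10",
) -> np.ndarray:
    """Latin hypercube start points inside the box, linear scale returned.

    Per dimension exactly one point falls in each of the n equal strata of
    the (log-scaled, if requested) box.  Deterministic given ``seed``.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if n < 1:
        raise ValueError("need n >= 1")
    if np.any(lower >= upper):
        raise ValueError("degenerate bounds")
    if scale == "log10":
        lo, hi = np.log10(lower), np.log10(upper)
    else:
        lo, hi = lower, upper
    sampler = qmc.LatinHypercube(d=lower.size, seed=seed)
    unit = sampler.random(n)
    pts = qmc.scale(unit, lo, hi)
    return 10.0 ** pts if scale == "log10" else pts


def _run_trust_region(problem: EstimationProblem, z0, lb, ub, counter):
    cm, data = problem.cm, problem.data

    def residuals(z):
        theta = problem.to_linear(z)
        counter["n_solves"] += 1
        traj = simulate(cm, theta, data.times, problem.solver_settings)
        return -negloglik(traj, data).residual_vector  # r = (y - ybar)/sigma

    def jac(z):
        theta = problem.to_linear(z)
        counter["n_solves"] += 1
        traj, fs = forward_sensitivities(
            cm, theta, data.times, problem.solver_settings
        )
        # d r / d theta = s^y / sigma on observed entries
        rows = []
        for j in range(data.times.size):
            for i in range(data.n_y):
                if data.mask[i, j]:
                    rows.append(fs.output_sens[j, i, :] / data.sigmas[i, j])
        J = np.asarray(rows)
        if problem.scale == "log10":
            J = J * theta * np.log(10.0)
        return J

    res = least_squares(
        residuals,
        z0,
        jac=jac,
        bounds=(lb, ub),
        method="trf",
        max_nfev=problem.max_iter,
        xtol=1e-10,
        ftol=1e-10,
        gtol=1e-8,
    )
    n_iter = int(res.nfev)
    status = "converged" if res.status > 0 else "budget"
    # least_squares cost is 0.5 * sum(r^2), i.e. exactly J
    return res.x, float(res.cost), n_iter, status


def _run_bfgs(problem: EstimationProblem, z0, lb, ub, counter, trace):
    cm, data = problem.cm, problem.data

    def fun(z):
        theta = problem.to_linear(z)
        res = gradient(
            cm,
            theta,
            data,
            method=problem.grad_method,
            settings=problem.solver_settings,
            scheme=problem.fd_scheme,
        )
        d = res.diagnostics
        counter["n_solves"] += d.get("n_simulations", 0) or (
            d.get("n_forward_solves", 0) + d.get("n_backward_solves", 0)
        )
        if not np.all(np.isfinite(res.grad)):
            raise SimulationError("gradient evaluation returned non-finite values")
        return res.J, problem.grad_to_internal(res.grad, theta)

    it_holder = {"i": 0}

    def cb(z):
        it_holder["i"] += 1
        theta = problem.to_linear(z)
        traj = simulate(cm, theta, data.times, problem.solver_settings)
        counter["n_solves"] += 1
        trace.append((it_holder["i"], negloglik(traj, data).J, counter["n_solves"]))

    res = minimize(
        fun,
        z0,
        jac=True,
        method="L-BFGS-B",
        bounds=list(zip(lb, ub)),
        callback=cb,
        options={"maxiter": problem.max_iter, "ftol": 1e-12, "gtol": 1e-9},
    )
    status = "converged" if res.success else "budget"
    return res.x, float(res.fun), int(res.nit), status


def optimize_local(problem: EstimationProblem, start: Sequence[float]) -> StartResult:
    """One bound-constrained local optimization from ``start`` (linear scale).

    A gradient/simulation failure at the very first evaluation yields a
    flagged ``gradient-failure`` result instead of an exception, so failed
    starts can be bookkept and excluded downstream.
    """
    start = np.asarray(start, dtype=float)
    if np.any(start < problem.lower) or np.any(start > problem.upper):
        raise ValueError("start point outside bounds")
    z0 = problem.to_internal(start)
    lb = problem.to_internal(problem.lower)
    ub = problem.to_internal(problem.upper)
    counter = {"n_solves": 0}
    trace: list[tuple[int, float, int]] = []

    try:
        J0 = negloglik(
            simulate(problem.cm, start, problem.data.times, problem.solver_settings),
            problem.data,
        ).J
        counter["n_solves"] += 1
        trace.append((0, J0, counter["n_solves"]))
        if problem.resolved_optimizer == "trust-region":
            z, J, n_iter, status = _run_trust_region(problem, z0, lb, ub, counter)
            J = negloglik(
                simulate(
                    problem.cm,
                    problem.to_linear(z),
                    problem.data.times,
                    problem.solver_settings,
                ),
                problem.data,
            ).J
            trace.append((n_iter, J, counter["n_solves"]))
        else:
            z, J, n_iter, status = _run_bfgs(problem, z0, lb, ub, counter, trace)
    except SimulationError as exc:
        return StartResult(
            start=start,
            theta=start.copy(),
            J=np.inf,
            iterations=0,
            converged="gradient-failure",
            trace=trace,
            message=str(exc),
        )

    theta = problem.to_linear(z)
    if J > J0:  # keep the best point seen; a converged run never worsens J
        theta, J = start.copy(), J0
    return StartResult(
        start=start,
        theta=theta,
        J=float(J),
        iterations=n_iter,
        converged=status,
        trace=trace,
    )


def multistart(
    problem: EstimationProblem, n_starts: int, seed: int
) -> MultiStartResult:
    """Run ``optimize_local`` from ``n_starts`` latin-hypercube start
    points and sort the results ascending by final J (failures last)."""
    starts = sample_starts(
        problem.lower, problem.upper, n_starts, seed, scale=problem.scale
    )
    results = [optimize_local(problem, s) for s in starts]
    results.sort(key=lambda r: (not r.ok, r.J))
    return MultiStartResult(
        starts=results,
        seed=seed,
        settings={
            "n_starts": n_starts,
            "grad_method": problem.grad_method,
            "optimizer": problem.resolved_optimizer,
            "scale": problem.scale,
            "max_iter": problem.max_iter,
            "rtol": problem.solver_settings.rtol,
            "atol": problem.solver_settings.atol,
        },
    )


def waterfall(result: MultiStartResult, tol: float = 1e-4) -> pd.DataFrame:
    """Sorted (rank, final J) table of successful starts; runs whose final
    J agree within ``tol`` are grouped as one optimum.  Failed starts are
    listed after the successful ones with NaN rank."""
    ok = [s for s in result.starts if s.ok]
    failed = [s for s in result.starts if not s.ok]
    rows = []
    group = 0
    last_J = None
    for rank, s in enumerate(sorted(ok, key=lambda r: r.J), start=1):
        if last_J is None or abs(s.J - last_J) > tol:
            group += 1
        last_J = s.J
        rows.append(
            {"rank": rank, "J": s.J, "optimum_group": group, "converged": s.converged}
        )
    for s in failed:
        rows.append(
            {"rank": np.nan, "J": np.nan, "optimum_group": np.nan,
             "converged": s.converged}
        )
    return pd.DataFrame(rows)
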