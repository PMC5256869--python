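"""Synthetic models and data: analytic oracles, the mRNA-transfection
model, random mass-action networks, and the Gaussian-noise data simulator.

The three named fixtures are small enough to have closed-form solutions
and serve as ground truth throughout the test suite:

* ``const`` — dx/dt = 0, x0 = theta, y = x (the objective is an exact
  quadratic in theta).
* ``decay`` — dx/dt = -k x, x0 = x0, y = x (single exponential).
* ``transfection`` — mRNA transfection: released mRNA m decays at rate
  deg_m and drives synthesis of a reporter G (rate k_syn) which decays at
  rate deg_G; the release of an amount m0 at time t_r is an instantaneous
  state jump.  Observed output is G.

Random networks are strictly mass-action (zeroth/first/second order
reactions), giving polynomial right-hand sides of degree <= 2; rate
constants are drawn log-uniformly.  Networks whose simulation blows up on
the screening horizon are rejected and redrawn, so every returned network
is integrable at its nominal parameters.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gradients import FdScheme, gradient
from .likelihood import ExperimentData
from .model import CompiledModel, EventSpec, OdeModel, compile_model
from .simulate import SimulationError, SolverSettings, simulate

__all__ = [
    "make_fixture",
    "NetworkSpec",
    "make_random_network",
    "generate_data",
    "scaling_experiment",
    "TRANSFECTION_THETA",
    "TRANSFECTION_RELEASE_TIME",
]

#: nominal transfection parameters (deg_m, k_syn, deg_G, m0): mRNA decays
#: on a ~1/h scale, the reporter more slowly, with a bolus of 2 units
TRANSFECTION_THETA = np.array([0.8, 1.2, 0.4, 2.0])
TRANSFECTION_RELEASE_TIME = 2.0


def make_fixture(name: str) -> OdeModel:
    """Return one of the named fixture models: const, decay, transfection."""
    if name == "const":
        return OdeModel(
            state_names=("x",),
            parameter_names=("theta",),
            observable_names=("y",),
            rhs=("0",),
            initial=("theta",),
            outputs=("x",),
            name="const",
        )
    if name == "decay":
        return OdeModel(
            state_names=("x",),
            parameter_names=("k", "x0"),
            observable_names=("y",),
            rhs=("-k*x",),
            initial=("x0",),
            outputs=("x",),
            name="decay",
        )
    if name == "transfection":
        return OdeModel(
            state_names=("m", "G"),
            parameter_names=("deg_m", "k_syn", "deg_G", "m0"),
            observable_names=("y",),
            rhs=("-deg_m*m", "k_syn*m - deg_G*G"),
            initial=("0", "0"),
            outputs=("G",),
            events=(EventSpec(TRANSFECTION_RELEASE_TIME, ("m + m0", "G")),),
            name="transfection",
        )
    raise ValueError(f"unknown fixture {name!r}; choose const, decay or transfection")


@dataclass(frozen=True)
class NetworkSpec:
    """Specification of a random mass-action network.

    ``n_r`` reactions are wired among ``n_x`` species with reaction orders
    drawn from ``allowed_orders``; each reaction gets its own rate constant
    drawn log-uniformly from ``rate_range``, so n_theta = n_r.
    """

    n_x: int
    n_r: int
    seed: int
    allowed_orders: tuple[int, ...] = (0, 1, 2)
    rate_range: tuple[float, float] = (1e-2, 1.0)

    def __post_init__(self) -> None:
        if self.n_x < 1:
            raise ValueError("need at least one species")
        if self.n_r < self.n_x - 1:
            raise ValueError(
                f"n_r={self.n_r} too small: need >= n_x - 1 = {self.n_x - 1} "
                "so every species can be produced or consumed"
            )
        if not set(self.allowed_orders) <= {0, 1, 2}:
            raise ValueError("allowed reaction orders are 0, 1 and 2")
        lo, hi = self.rate_range
        if not (0 < lo < hi):
            raise ValueError("rate_range must be 0 < lo < hi")


def _draw_reactions(spec: NetworkSpec, rng: np.random.Generator):
    """Reaction list [(reactants, products, rate_name)] with nonzero net
    stoichiometry per reaction so every rate constant appears in the rhs."""
    reactions = []
    for r in range(spec.n_r):
        for _ in range(100):
            order = int(rng.choice(spec.allowed_orders))
            reactants = list(rng.choice(spec.n_x, size=order, replace=True))
            n_prod = int(rng.integers(0, 3)) if order > 0 else int(rng.integers(1, 3))
            products = list(rng.choice(spec.n_x, size=n_prod, replace=True))
            net = np.zeros(spec.n_x)
            for s in reactants:
                net[s] -= 1
            for s in products:
                net[s] += 1
            if np.any(net != 0):
                reactions.append((reactants, products, f"k{r + 1}"))
                break
        else:  # pragma: no cover - combinatorially implausible
            raise RuntimeError("could not draw a reaction with nonzero net effect")
    # every species must take part in some reaction
    touched = set()
    for reactants, products, _ in reactions:
        touched.update(reactants)
        touched.update(products)
    return reactions if touched == set(range(spec.n_x)) else None


def _network_from_reactions(spec: NetworkSpec, reactions, rates, x0, outputs):
    species = [f"x{i + 1}" for i in range(spec.n_x)]
    terms: list[list[str]] = [[] for _ in range(spec.n_x)]
    for reactants, products, kname in reactions:
        flux = kname
        for s in reactants:
            flux += f"*{species[s]}"
        net = np.zeros(spec.n_x, dtype=int)
        for s in reactants:
            net[s] -= 1
        for s in products:
            net[s] += 1
        for i in range(spec.n_x):
            if net[i] > 0:
                terms[i].append(f"+ {net[i]}*{flux}" if net[i] > 1 else f"+ {flux}")
            elif net[i] < 0:
                terms[i].append(f"- {-net[i]}*{flux}" if net[i] < -1 else f"- {flux}")
    rhs = [" ".join(t) if t else "0" for t in terms]
    return OdeModel(
        state_names=tuple(species),
        parameter_names=tuple(k for _, _, k in reactions),
        observable_names=tuple(f"obs_{species[i]}" for i in outputs),
        rhs=tuple(rhs),
        initial=tuple(repr(float(v)) for v in x0),
        outputs=tuple(species[i] for i in outputs),
        name=f"random_net_seed{spec.seed}",
    )


def make_random_network(
    spec: NetworkSpec,
    screen_horizon: float = 10.0,
    max_attempts: int = 50,
) -> tuple[OdeModel, np.ndarray]:
    """Draw a random mass-action network and its nominal rate constants.

    Deterministic given ``spec.seed``.  Candidate networks whose nominal
    simulation on [t0, screen_horizon] fails or exceeds 1e6 in magnitude
    are rejected and redrawn from the same stream, so finite-time blow-ups
    never escape the generator.

    Returns ``(model, theta_nominal)``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.rate_range
    for _attempt in range(max_attempts):
        reactions = _draw_reactions(spec, rng)
        if reactions is None:
            continue
        rates = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_r))
        x0 = np.round(rng.uniform(0.5, 2.0, size=spec.n_x), 6)
        n_out = int(rng.integers(1, spec.n_x + 1))
        outputs = sorted(rng.choice(spec.n_x, size=n_out, replace=False).tolist())
        model = _network_from_reactions(spec, reactions, rates, x0, outputs)
        try:
            cm = compile_model(model)
            times = np.linspace(0.0, screen_horizon, 11)
            traj = simulate(cm, rates, times, SolverSettings())
        except SimulationError:
            continue
        if np.max(np.abs(traj.states)) > 1e6:
            continue
        return model, rates
    raise RuntimeError(
        f"no integrable network found in {max_attempts} draws for seed {spec.seed}"
    )


def generate_data(
    cm: CompiledModel,
    theta_true: Sequence[float],
    times: Sequence[float],
    sigma: float | Sequence[float] | np.ndarray = 0.1,
    seed: int = 0,
    missing_fraction: float = 0.0,
    settings: SolverSettings | None = None,
) -> ExperimentData:
    """Simulate at ``theta_true`` and corrupt with independent Gaussian
    noise: ybar_ij = y_i(t_j) + eps_ij, eps_ij ~ N(0, sigma_ij^2).

    ``missing_fraction`` of the grid entries are masked uniformly at
    random (exactly round(frac * n) entries).  Bit-for-bit reproducible
    given ``seed``.
    """
    times = np.asarray(times, dtype=float)
    traj = simulate(cm, theta_true, times, settings)
    y = traj.outputs.T  # (n_y, N)
    rng = np.random.default_rng(seed)
    sig = np.broadcast_to(
        np.asarray(sigma, dtype=float).reshape(-1, 1)
        if np.ndim(sigma) == 1
        else np.asarray(sigma, dtype=float),
        y.shape,
    )
    values = y + sig * rng.standard_normal(y.shape) if np.any(sig > 0) else y.copy()
    values = np.where(sig > 0, values, y)
    mask = np.ones(y.shape, dtype=bool)
    if missing_fraction > 0:
        n_total = y.size
        n_miss = int(round(missing_fraction * n_total))
        flat = rng.choice(n_total, size=n_miss, replace=False)
        mask.flat[flat] = False
    # sigma must be positive wherever observed; noise-free data uses a
    # nominal unit sigma for weighting
    sig_out = np.where(sig > 0, sig, 1.0)
    return ExperimentData(times=times, values=values, sigmas=sig_out, mask=mask)


def scaling_experiment(
    cm: CompiledModel,
    theta: Sequence[float],
    data: ExperimentData,
    subset_sizes: Sequence[int],
    methods: Sequence[str] = ("fd", "forward", "adjoint"),
    repeats: int = 1,
    settings: SolverSettings | None = None,
    scheme: FdScheme | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Time each gradient engine over nested random parameter subsets.

    Returns a table with one row per (method, subset size) holding mean
    wall time, simulation counts, backward-solve counts and the forward
    augmented dimension, so structural scaling claims can be asserted
    without timing.  Failures are recorded per cell, not raised.
    """
    theta = np.asarray(theta, dtype=float)
    rng = np.random.default_rng(seed)
    order = rng.permutation(cm.n_theta)
    rows = []
    for k in subset_sizes:
        if k > cm.n_theta:
            raise ValueError(f"subset size {k} exceeds n_theta={cm.n_theta}")
        subset = np.sort(order[:k])
        for method in methods:
            times_s, res, err = [], None, None
            for _ in range(repeats):
                t0 = _time.perf_counter()
                try:
                    res = gradient(
                        cm, theta, data, method=method,
                        settings=settings, subset=subset, scheme=scheme,
                    )
                except SimulationError as exc:
                    err = str(exc)
                    break
                times_s.append(_time.perf_counter() - t0)
            row = {
                "method": method,
                "subset_size": k,
                "mean_time_s": float(np.mean(times_s)) if times_s else np.nan,
                "failed": err is not None,
                "error": err,
            }
            if res is not None and err is None:
                d = res.diagnostics
                row.update(
                    n_simulations=d.get("n_simulations", d.get("n_forward_solves", 0)),
                    n_backward_solves=d.get("n_backward_solves", 0),
                    augmented_dim=d.get("augmented_dim", cm.n_x),
                )
            rows.append(row)
    return pd.DataFrame(rows)
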