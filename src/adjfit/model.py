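"""Symbolic definition of ODE reaction-network models and derivative compilation.

A model is the initial value problem

    dx/dt = f(x, theta),   x(t0) = x0(theta),

observed through an output map y = h(x, theta), optionally interrupted by
fixed-time state-jump events x(te+) = g(x(te-), theta) (e.g. instantaneous
release of material at a known time).  :func:`compile_model` turns the
symbolic definition into fast numerical callables for the right-hand side,
the output map and every partial derivative the downstream gradient engines
need (df/dx, df/dtheta, dh/dx, dh/dtheta, dx0/dtheta and, per event, dg/dx
and dg/dtheta), all generated by exact symbolic differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import sympy as sp
from sympy.core.function import AppliedUndef
from sympy.parsing.sympy_parser import (
    convert_xor,
    parse_expr,
    standard_transformations,
)

__all__ = [
    "OdeModel",
    "EventSpec",
    "CompiledModel",
    "ModelDefinitionError",
    "compile_model",
]


class ModelDefinitionError(ValueError):
    """Raised when a model definition cannot be parsed or is inconsistent."""


#: functions admitted by the expression grammar (plus +, -, *, /, ^ and
#: rational terms built from them, covering mass-action, Michaelis-Menten
#: and Hill kinetics)
_ALLOWED_FUNCTIONS: dict[str, sp.Function] = {
    "exp": sp.exp,
    "log": sp.log,
    "ln": sp.log,
    "sqrt": sp.sqrt,
}

_TRANSFORMATIONS = standard_transformations + (convert_xor,)

# names the tokenizer itself needs to build unknown symbols/functions
_GLOBAL_DICT = {
    "Symbol": sp.Symbol,
    "Function": sp.Function,
    "Integer": sp.Integer,
    "Float": sp.Float,
    "Rational": sp.Rational,
}


def parse_expression(text: str, symbols: dict[str, sp.Symbol]) -> sp.Expr:
    """Parse one scalar expression over the given symbols.

    The grammar is arithmetic (``+ - * / ^``/``**``), ``exp``, ``log`` and
    ``sqrt``; any other function or identifier is rejected with the
    offending name.
    """
    local = dict(symbols)
    local.update(_ALLOWED_FUNCTIONS)
    try:
        expr = parse_expr(
            str(text),
            local_dict=local,
            global_dict=_GLOBAL_DICT,
            transformations=_TRANSFORMATIONS,
            evaluate=True,
        )
    except (SyntaxError, TypeError, ValueError) as exc:
        raise ModelDefinitionError(f"cannot parse expression {text!r}: {exc}") from exc
    if isinstance(expr, sp.Basic):
        unknown = {str(s) for s in expr.free_symbols} - set(symbols)
        if unknown:
            raise ModelDefinitionError(
                f"unknown identifier(s) {sorted(unknown)} in expression {text!r}"
            )
        bad_funcs = {
            type(f).__name__ for f in expr.atoms(AppliedUndef)
        }
        if bad_funcs:
            raise ModelDefinitionError(
                f"unknown function(s) {sorted(bad_funcs)} in expression {text!r}"
            )
    else:
        raise ModelDefinitionError(f"expression {text!r} is not scalar")
    if expr.has(sp.I) or not expr.is_commutative:
        raise ModelDefinitionError(f"expression {text!r} is not a real scalar")
    return expr


@dataclass(frozen=True)
class EventSpec:
    """Fixed-time state jump: at ``time``, the state is reassigned to
    ``assignment`` evaluated at the pre-event state (identity entries allowed).

    Event times are plain numbers, never parameter expressions.
    """

    time: float
    assignment: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", float(self.time))
        object.__setattr__(self, "assignment", tuple(str(a) for a in self.assignment))


@dataclass(frozen=True)
class OdeModel:
    """Symbolic ODE model: states, parameters, observables and expressions.

    ``rhs``, ``initial`` and ``outputs`` are scalar expression strings over
    the declared identifiers; ``initial`` may reference parameters only.
    """

    state_names: tuple[str, ...]
    parameter_names: tuple[str, ...]
    observable_names: tuple[str, ...]
    rhs: tuple[str, ...]
    initial: tuple[str, ...]
    outputs: tuple[str, ...]
    events: tuple[EventSpec, ...] = ()
    t0: float = 0.0
    name: str = "model"

    def __post_init__(self) -> None:
        object.__setattr__(self, "state_names", tuple(self.state_names))
        object.__setattr__(self, "parameter_names", tuple(self.parameter_names))
        object.__setattr__(self, "observable_names", tuple(self.observable_names))
        object.__setattr__(self, "rhs", tuple(str(e) for e in self.rhs))
        object.__setattr__(self, "initial", tuple(str(e) for e in self.initial))
        object.__setattr__(self, "outputs", tuple(str(e) for e in self.outputs))
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(self, "t0", float(self.t0))
        self._validate()

    @property
    def n_x(self) -> int:
        return len(self.state_names)

    @property
    def n_theta(self) -> int:
        return len(self.parameter_names)

    @property
    def n_y(self) -> int:
        return len(self.observable_names)

    def _validate(self) -> None:
        if self.n_x < 1 or self.n_theta < 1 or self.n_y < 1:
            raise ModelDefinitionError("need at least one state, parameter and observable")
        all_names = self.state_names + self.parameter_names
        if len(set(all_names)) != len(all_names):
            dupes = sorted({n for n in all_names if all_names.count(n) > 1})
            raise ModelDefinitionError(f"duplicate identifier(s): {dupes}")
        if len(set(self.observable_names)) != len(self.observable_names):
            raise ModelDefinitionError("observable names must be unique")
        if len(self.rhs) != self.n_x:
            raise ModelDefinitionError(
                f"rhs has {len(self.rhs)} expressions for {self.n_x} states"
            )
        if len(self.initial) != self.n_x:
            raise ModelDefinitionError(
                f"initial has {len(self.initial)} expressions for {self.n_x} states"
            )
        if len(self.outputs) != self.n_y:
            raise ModelDefinitionError(
                f"outputs has {len(self.outputs)} expressions for {self.n_y} observables"
            )
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ModelDefinitionError("event times must be strictly increasing")
        if any(t <= self.t0 for t in times):
            raise ModelDefinitionError("event times must be > t0")
        for ev in self.events:
            if len(ev.assignment) != self.n_x:
                raise ModelDefinitionError(
                    f"event at t={ev.time} assigns {len(ev.assignment)} states, "
                    f"model has {self.n_x}"
                )


def _lambdify_matrix(
    x_syms: Sequence[sp.Symbol],
    th_syms: Sequence[sp.Symbol],
    mat: sp.Matrix,
    shape: tuple[int, ...],
) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    fn = sp.lambdify((tuple(x_syms), tuple(th_syms)), mat, modules="numpy")

    def wrapped(x: np.ndarray, theta: np.ndarray) -> np.ndarray:
        out = np.asarray(fn(tuple(x), tuple(theta)), dtype=float)
        return out.reshape(shape)

    return wrapped


def _lambdify_theta_only(
    th_syms: Sequence[sp.Symbol], mat: sp.Matrix, shape: tuple[int, ...]
) -> Callable[[np.ndarray], np.ndarray]:
    fn = sp.lambdify((tuple(th_syms),), mat, modules="numpy")

    def wrapped(theta: np.ndarray) -> np.ndarray:
        return np.asarray(fn(tuple(theta)), dtype=float).reshape(shape)

    return wrapped


@dataclass(frozen=True)
class CompiledEvent:
    time: float
    g: Callable[[np.ndarray, np.ndarray], np.ndarray]          # (n_x,)
    G_x: Callable[[np.ndarray, np.ndarray], np.ndarray]        # (n_x, n_x)
    G_theta: Callable[[np.ndarray, np.ndarray], np.ndarray]    # (n_x, n_theta)


@dataclass(frozen=True)
class CompiledModel:
    """Numerical callables generated from an :class:`OdeModel`.

    All derivative callables are exact symbolic derivatives of the parsed
    expression trees; evaluation is pure and repeatable.
    """

    model: OdeModel
    f: Callable[[np.ndarray, np.ndarray], np.ndarray]          # (n_x,)
    x0: Callable[[np.ndarray], np.ndarray]                      # (n_x,)
    h: Callable[[np.ndarray, np.ndarray], np.ndarray]          # (n_y,)
    J_x: Callable[[np.ndarray, np.ndarray], np.ndarray]        # (n_x, n_x)
    J_theta: Callable[[np.ndarray, np.ndarray], np.ndarray]    # (n_x, n_theta)
    H_x: Callable[[np.ndarray, np.ndarray], np.ndarray]        # (n_y, n_x)
    H_theta: Callable[[np.ndarray, np.ndarray], np.ndarray]    # (n_y, n_theta)
    X0_theta: Callable[[np.ndarray], np.ndarray]                # (n_x, n_theta)
    events: tuple[CompiledEvent, ...] = ()

    @property
    def n_x(self) -> int:
        return self.model.n_x

    @property
    def n_theta(self) -> int:
        return self.model.n_theta

    @property
    def n_y(self) -> int:
        return self.model.n_y

    @property
    def t0(self) -> float:
        return self.model.t0


def compile_model(model: OdeModel) -> CompiledModel:
    """Parse all expressions of ``model`` and generate derivative callables.

    Raises :class:`ModelDefinitionError` naming the offending expression or
    identifier on any parse/definition problem.
    """
    x_syms = [sp.Symbol(n, real=True) for n in model.state_names]
    th_syms = [sp.Symbol(n, real=True) for n in model.parameter_names]
    full_ns = {str(s): s for s in (*x_syms, *th_syms)}
    theta_ns = {str(s): s for s in th_syms}

    f_exprs = sp.Matrix([parse_expression(e, full_ns) for e in model.rhs])
    h_exprs = sp.Matrix([parse_expression(e, full_ns) for e in model.outputs])
    x0_exprs = sp.Matrix([parse_expression(e, theta_ns) for e in model.initial])

    n_x, n_th, n_y = model.n_x, model.n_theta, model.n_y
    x_vec = sp.Matrix(x_syms)
    th_vec = sp.Matrix(th_syms)

    Jx = f_exprs.jacobian(x_vec)
    Jth = f_exprs.jacobian(th_vec)
    Hx = h_exprs.jacobian(x_vec)
    Hth = h_exprs.jacobian(th_vec)
    X0th = x0_exprs.jacobian(th_vec)

    events = []
    for ev in model.events:
        g_exprs = sp.Matrix([parse_expression(e, full_ns) for e in ev.assignment])
        events.append(
            CompiledEvent(
                time=ev.time,
                g=_lambdify_matrix(x_syms, th_syms, g_exprs, (n_x,)),
                G_x=_lambdify_matrix(x_syms, th_syms, g_exprs.jacobian(x_vec), (n_x, n_x)),
                G_theta=_lambdify_matrix(
                    x_syms, th_syms, g_exprs.jacobian(th_vec), (n_x, n_th)
                ),
            )
        )

    return CompiledModel(
        model=model,
        f=_lambdify_matrix(x_syms, th_syms, f_exprs, (n_x,)),
        x0=_lambdify_theta_only(th_syms, x0_exprs, (n_x,)),
        h=_lambdify_matrix(x_syms, th_syms, h_exprs, (n_y,)),
        J_x=_lambdify_matrix(x_syms, th_syms, Jx, (n_x, n_x)),
        J_theta=_lambdify_matrix(x_syms, th_syms, Jth, (n_x, n_th)),
        H_x=_lambdify_matrix(x_syms, th_syms, Hx, (n_y, n_x)),
        H_theta=_lambdify_matrix(x_syms, th_syms, Hth, (n_y, n_th)),
        X0_theta=_lambdify_theta_only(th_syms, X0th, (n_x, n_th)),
        events=tuple(events),
    )
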