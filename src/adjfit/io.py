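"""Readers and writers: native model format, SBML subset, measurement
tables and result serialization.

The native model format is a YAML/JSON document with keys ``states``,
``parameters``, ``observables``, ``rhs``, ``initial``, ``outputs``,
``events`` (list of ``{time, assign: {state: expression}}``; unlisted
states keep their value) and optional ``t0``/``name``.  Measurement
tables are long-format CSV/TSV with columns ``time``, ``observable``,
``value`` and optional ``sigma``; absent rows are missing values.

The SBML reader covers a deliberate subset — reactions folded to ODEs via
stoichiometry, compartments folded to volumes, initial amounts and
concentrations — and rejects trigger-based events, rules, delays and
function definitions by name.  The tested, canonical path is the native
format.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .estimation import MultiStartResult, StartResult
from .gradients import GradientResult
from .likelihood import DataError, ExperimentData
from .model import EventSpec, ModelDefinitionError, OdeModel

__all__ = [
    "read_model",
    "write_model",
    "read_data",
    "write_data",
    "read_sbml",
    "UnsupportedConstructError",
    "gradient_result_to_dict",
    "write_gradient_result",
    "multistart_to_dict",
    "write_multistart_result",
    "read_multistart_result",
]


class UnsupportedConstructError(ModelDefinitionError):
    """An SBML construct outside the supported subset, named explicitly."""


# ---------------------------------------------------------------------------
# native model format
# ---------------------------------------------------------------------------

def model_to_dict(model: OdeModel) -> dict:
    events = []
    for ev in model.events:
        assign = {
            s: expr
            for s, expr in zip(model.state_names, ev.assignment)
            if expr != s  # identity assignments are implicit
        }
        events.append({"time": ev.time, "assign": assign})
    return {
        "name": model.name,
        "t0": model.t0,
        "states": list(model.state_names),
        "parameters": list(model.parameter_names),
        "observables": list(model.observable_names),
        "rhs": list(model.rhs),
        "initial": list(model.initial),
        "outputs": list(model.outputs),
        "events": events,
    }


def model_from_dict(doc: dict) -> OdeModel:
    required = {"states", "parameters", "rhs", "initial", "outputs"}
    missing = required - set(doc)
    if missing:
        raise ModelDefinitionError(f"model document missing keys: {sorted(missing)}")
    states = [str(s) for s in doc["states"]]
    observables = [str(o) for o in doc.get("observables", [])] or [
        f"y{i + 1}" for i in range(len(doc["outputs"]))
    ]
    events = []
    for ev in doc.get("events", []):
        assign = ev.get("assign", {})
        unknown = set(assign) - set(states)
        if unknown:
            raise ModelDefinitionError(
                f"event assigns unknown state(s): {sorted(unknown)}"
            )
        full = tuple(str(assign.get(s, s)) for s in states)
        events.append(EventSpec(time=float(ev["time"]), assignment=full))
    return OdeModel(
        state_names=tuple(states),
        parameter_names=tuple(str(p) for p in doc["parameters"]),
        observable_names=tuple(observables),
        rhs=tuple(str(e) for e in doc["rhs"]),
        initial=tuple(str(e) for e in doc["initial"]),
        outputs=tuple(str(e) for e in doc["outputs"]),
        events=tuple(events),
        t0=float(doc.get("t0", 0.0)),
        name=str(doc.get("name", "model")),
    )


def write_model(model: OdeModel, path: str | Path) -> None:
    """Write a model in the native format; .json writes JSON, else YAML."""
    path = Path(path)
    doc = model_to_dict(model)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def read_model(path: str | Path, format: str | None = None) -> OdeModel:
    """Read a model: native YAML/JSON (``format='native'``) or SBML subset
    (``format='sbml'``).  The format is inferred from the suffix when not
    given (.xml/.sbml -> SBML)."""
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "native"
    if format == "sbml":
        return read_sbml(path)
    if format != "native":
        raise ValueError(f"unknown model format {format!r}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ModelDefinitionError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ModelDefinitionError(f"{path} does not contain a model document")
    return model_from_dict(doc)


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------

def read_data(
    path: str | Path,
    observables: Sequence[str] | None = None,
    default_sigma: float | None = None,
) -> ExperimentData:
    """Read a long-format CSV/TSV measurement table.

    Columns: ``time``, ``observable``, ``value`` and optionally ``sigma``
    (falling back to ``default_sigma``).  Rows absent from the full
    time x observable grid become masked (missing) entries.  ``observables``
    fixes the observable ordering (and catches typos); duplicated
    (time, observable) rows are rejected.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    needed = {"time", "observable", "value"}
    if not needed <= set(df.columns):
        raise DataError(
            f"{path} must have columns {sorted(needed)}, found {list(df.columns)}"
        )
    if "sigma" not in df.columns:
        if default_sigma is None:
            raise DataError(
                f"{path} has no sigma column and no default_sigma was given"
            )
        df = df.assign(sigma=float(default_sigma))
    df["sigma"] = df["sigma"].fillna(
        default_sigma if default_sigma is not None else np.nan
    )
    if df.duplicated(subset=["time", "observable"]).any():
        dupes = df[df.duplicated(subset=["time", "observable"], keep=False)]
        raise DataError(
            f"duplicate (time, observable) rows in {path}: "
            f"{dupes[['time', 'observable']].drop_duplicates().to_dict('records')}"
        )
    obs_in_file = list(dict.fromkeys(df["observable"]))
    if observables is None:
        observables = obs_in_file
    else:
        unknown = set(obs_in_file) - set(observables)
        if unknown:
            raise DataError(f"unknown observable name(s): {sorted(unknown)}")
    times = np.array(sorted(df["time"].unique()), dtype=float)
    n_y, n_t = len(observables), times.size
    values = np.full((n_y, n_t), np.nan)
    sigmas = np.ones((n_y, n_t))
    t_index = {t: j for j, t in enumerate(times)}
    o_index = {o: i for i, o in enumerate(observables)}
    for row in df.itertuples(index=False):
        i, j = o_index[row.observable], t_index[float(row.time)]
        values[i, j] = row.value
        if np.isfinite(row.sigma):
            sigmas[i, j] = row.sigma
    return ExperimentData(times=times, values=values, sigmas=sigmas)


def write_data(
    data: ExperimentData, path: str | Path, observables: Sequence[str] | None = None
) -> None:
    """Write observed entries as a long-format CSV/TSV table."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    observables = list(observables) if observables is not None else [
        f"y{i + 1}" for i in range(data.n_y)
    ]
    rows = []
    for i in range(data.n_y):
        for j in range(data.n_times):
            if data.mask[i, j]:
                rows.append(
                    {
                        "time": data.times[j],
                        "observable": observables[i],
                        "value": data.values[i, j],
                        "sigma": data.sigmas[i, j],
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# SBML subset
# ---------------------------------------------------------------------------

_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _mathml_to_expr(node: ET.Element, rename: dict[str, str]) -> str:
    """Translate a content-MathML tree into the native expression grammar."""
    tag = _strip_ns(node.tag)
    if tag == "math":
        children = list(node)
        if len(children) != 1:
            raise UnsupportedConstructError("math element must contain one expression")
        return _mathml_to_expr(children[0], rename)
    if tag == "ci":
        name = (node.text or "").strip()
        return rename.get(name, name)
    if tag == "cn":
        parts = [(node.text or "").strip()]
        for child in node:
            if _strip_ns(child.tag) == "sep":
                parts.append((child.tail or "").strip())
        if node.get("type") == "e-notation" and len(parts) == 2:
            return f"({parts[0]}e{parts[1]})"
        if node.get("type") == "rational" and len(parts) == 2:
            return f"({parts[0]}/{parts[1]})"
        return parts[0]
    if tag == "csymbol":
        raise UnsupportedConstructError(
            f"csymbol ({(node.text or '').strip()}) is not supported"
        )
    if tag != "apply":
        raise UnsupportedConstructError(f"MathML element <{tag}> is not supported")
    children = list(node)
    op = _strip_ns(children[0].tag)
    args = [_mathml_to_expr(c, rename) for c in children[1:]]
    if op == "plus":
        return "(" + " + ".join(args) + ")" if args else "0"
    if op == "minus":
        return f"(-{args[0]})" if len(args) == 1 else f"({args[0]} - {args[1]})"
    if op == "times":
        return "(" + " * ".join(args) + ")" if args else "1"
    if op == "divide":
        return f"({args[0]} / {args[1]})"
    if op == "power":
        return f"({args[0]})^({args[1]})"
    if op == "exp":
        return f"exp({args[0]})"
    if op == "ln":
        return f"log({args[0]})"
    if op == "log":
        # default base 10 unless an explicit logbase child was present
        return f"(log({args[-1]}) / log(10))"
    if op == "root":
        return f"sqrt({args[-1]})"
    raise UnsupportedConstructError(f"MathML operator <{op}> is not supported")


def read_sbml(path: str | Path) -> OdeModel:
    """Read an SBML file within the supported subset and fold reactions
    into ODEs (dx/dt = (1/V) * S * flux).

    Rejected constructs (by name): events with triggers, any rule type,
    function definitions, delayed or fast reactions, species with
    boundaryCondition.  Constant parameters become model parameters;
    compartment sizes fold into concentration rates.  Outputs default to
    all non-constant species.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ModelDefinitionError(f"cannot parse SBML file {path}: {exc}") from exc
    sbml = tree.getroot()
    model_el = next((c for c in sbml if _strip_ns(c.tag) == "model"), None)
    if model_el is None:
        raise ModelDefinitionError(f"{path} has no <model> element")

    def find_list(name):
        el = next((c for c in model_el if _strip_ns(c.tag) == name), None)
        return list(el) if el is not None else []

    for bad, label in (
        ("listOfEvents", "events with triggers"),
        ("listOfRules", "rules (assignment/rate/algebraic)"),
        ("listOfFunctionDefinitions", "function definitions"),
        ("listOfConstraints", "constraints"),
    ):
        if find_list(bad):
            raise UnsupportedConstructError(f"unsupported SBML construct: {label}")

    compartments = {}
    for comp in find_list("listOfCompartments"):
        compartments[comp.get("id")] = float(comp.get("size", 1.0) or 1.0)

    species_order: list[str] = []
    initial: dict[str, float] = {}
    spec_compartment: dict[str, str] = {}
    for spc in find_list("listOfSpecies"):
        sid = spc.get("id")
        if spc.get("boundaryCondition", "false") == "true":
            raise UnsupportedConstructError(
                f"unsupported SBML construct: boundary species ({sid})"
            )
        if spc.get("constant", "false") == "true":
            raise UnsupportedConstructError(
                f"unsupported SBML construct: constant species ({sid})"
            )
        species_order.append(sid)
        spec_compartment[sid] = spc.get("compartment", "")
        if spc.get("initialConcentration") is not None:
            initial[sid] = float(spc.get("initialConcentration"))
        elif spc.get("initialAmount") is not None:
            vol = compartments.get(spec_compartment[sid], 1.0)
            initial[sid] = float(spc.get("initialAmount")) / vol
        else:
            initial[sid] = 0.0

    parameters: list[str] = []
    param_values: dict[str, float] = {}
    for par in find_list("listOfParameters"):
        pid = par.get("id")
        parameters.append(pid)
        if par.get("value") is not None:
            param_values[pid] = float(par.get("value"))

    # compartment sizes referenced inside kinetic laws become numbers
    rename = {cid: repr(size) for cid, size in compartments.items()}

    terms: dict[str, list[str]] = {s: [] for s in species_order}
    for ri, rxn in enumerate(find_list("listOfReactions")):
        if rxn.get("fast", "false") == "true":
            raise UnsupportedConstructError(
                f"unsupported SBML construct: fast reaction ({rxn.get('id')})"
            )
        kl = next((c for c in rxn if _strip_ns(c.tag) == "kineticLaw"), None)
        if kl is None:
            raise ModelDefinitionError(
                f"reaction {rxn.get('id')!r} has no kinetic law"
            )
        local_rename = dict(rename)
        for lp_list in kl:
            if _strip_ns(lp_list.tag) in ("listOfLocalParameters", "listOfParameters"):
                for lp in lp_list:
                    lid = lp.get("id")
                    new = f"{rxn.get('id', f'r{ri + 1}')}_{lid}"
                    local_rename[lid] = new
                    parameters.append(new)
                    if lp.get("value") is not None:
                        param_values[new] = float(lp.get("value"))
        math_el = next((c for c in kl if _strip_ns(c.tag) == "math"), None)
        if math_el is None:
            raise ModelDefinitionError(
                f"kinetic law of reaction {rxn.get('id')!r} has no math"
            )
        flux = _mathml_to_expr(math_el, local_rename)
        for role, sign in (("listOfReactants", -1), ("listOfProducts", +1)):
            role_el = next((c for c in rxn if _strip_ns(c.tag) == role), None)
            if role_el is None:
                continue
            for ref in role_el:
                sid = ref.get("species")
                stoich = float(ref.get("stoichiometry", 1.0) or 1.0)
                vol = compartments.get(spec_compartment.get(sid, ""), 1.0)
                coeff = sign * stoich / vol
                terms[sid].append(f"+ ({coeff!r})*({flux})")

    rhs = [" ".join(terms[s]) if terms[s] else "0" for s in species_order]
    model = OdeModel(
        state_names=tuple(species_order),
        parameter_names=tuple(parameters),
        observable_names=tuple(f"obs_{s}" for s in species_order),
        rhs=tuple(rhs),
        initial=tuple(repr(initial[s]) for s in species_order),
        outputs=tuple(species_order),
        name=model_el.get("id", path.stem),
    )
    return model


# ---------------------------------------------------------------------------
# result serialization (JSON)
# ---------------------------------------------------------------------------

def gradient_result_to_dict(res: GradientResult) -> dict:
    return {
        "J": res.J,
        "grad": res.grad.tolist(),
        "method": res.method,
        "param_subset": res.param_subset.tolist(),
        "diagnostics": {
            k: v for k, v in res.diagnostics.items() if _json_safe(v)
        },
    }


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def write_gradient_result(res: GradientResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(gradient_result_to_dict(res), indent=2) + "\n")


def _start_to_dict(s: StartResult) -> dict:
    return {
        "start": s.start.tolist(),
        "theta": s.theta.tolist(),
        "J": s.J,
        "iterations": s.iterations,
        "converged": s.converged,
        "trace": [list(t) for t in s.trace],
        "message": s.message,
    }


def multistart_to_dict(res: MultiStartResult) -> dict:
    return {
        "seed": res.seed,
        "settings": res.settings,
        "starts": [_start_to_dict(s) for s in res.starts],
    }


def write_multistart_result(res: MultiStartResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(multistart_to_dict(res), indent=2) + "\n")


def read_multistart_result(path: str | Path) -> MultiStartResult:
    doc = json.loads(Path(path).read_text())
    starts = [
        StartResult(
            start=np.asarray(s["start"]),
            theta=np.asarray(s["theta"]),
            J=s["J"],
            iterations=s["iterations"],
            converged=s["converged"],
            trace=[tuple(t) for t in s["trace"]],
            message=s.get("message", ""),
        )
        for s in doc["starts"]
    ]
    return MultiStartResult(starts=starts, seed=doc["seed"], settings=doc["settings"])
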