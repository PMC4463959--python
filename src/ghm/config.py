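"""Declarative problem and run configuration parsing.

Problems can be defined without touching code, in a flat YAML document::

    unknowns: [y]
    independent: t
    equations: ["y'' + kappa*(1 + y + y**2/2 + y**3/6)"]   # "= 0" implied
    conditions:
      - {unknown: y, order: 0, at: 0, value: 0}
      - {unknown: y, order: 0, at: 1, value: 0}
    parameters: {kappa: 1}
    interval: [0, 1]

Equations use prime notation for derivatives (``y''``) and bare unknown
names; both are rewritten to applied functions before sympification.  A run
configuration wraps a problem (by built-in name or inline), an ansatz spec
(``{numerator: [0,1], denominator: [2]}`` or ``{even_odd: 6}``), the
homotopy operators for inline problems, the control parameter (fixed value
or sweep grid), and validation settings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import sympy as sp
import yaml

from .case_studies import CASE_STUDIES, HBAR, get_case_study
from .homotopy import HomotopyConfig, RationalAnsatz, make_ansatz
from .problems import ODESystemProblem, PointCondition, exact

__all__ = [
    "parse_expression",
    "problem_from_dict",
    "homotopy_from_dict",
    "ansatz_from_spec",
    "RunConfig",
    "load_run_config",
    "CASE_ALIASES",
]

CASE_ALIASES = {
    "gelfand": "gelfand",
    "heat": "heat_radiation",
    "heat_radiation": "heat_radiation",
    "smoking": "smoking_spain",
    "smoking_spain": "smoking_spain",
}


def parse_expression(
    text: str,
    unknowns,
    independent: str,
    parameters=(),
) -> sp.Expr:
    """Parse an equation string with prime-notation derivatives.

    ``y''`` becomes ``Derivative(y(t), (t, 2))`` and bare ``y`` becomes
    ``y(t)``; parameter names stay plain symbols.  A trailing ``= 0`` (or any
    ``lhs = rhs``) is folded into a residual ``lhs - rhs``.
    """
    x = sp.Symbol(independent)
    if "=" in text:
        lhs, rhs = text.split("=", 1)
        text = f"({lhs}) - ({rhs})"
    locals_: dict = {independent: x}
    for p in parameters:
        locals_[str(p)] = sp.Symbol(str(p))
    work = text
    for name in sorted(unknowns, key=len, reverse=True):
        work = re.sub(
            rf"\b{re.escape(name)}('+)",
            lambda m, n=name: f"Derivative({n}({independent}),({independent},{len(m.group(1))}))",
            work,
        )
        work = re.sub(rf"\b{re.escape(name)}\b(?!\()", f"{name}({independent})", work)
        locals_[name] = sp.Function(name)
    return sp.sympify(work, locals=locals_)


def problem_from_dict(spec: Mapping) -> ODESystemProblem:
    """Build a problem from the declarative mapping shown in the module docs."""
    unknowns = list(spec["unknowns"])
    independent = spec.get("independent", "t")
    parameters = dict(spec.get("parameters", {}) or {})
    residuals = [
        parse_expression(eq, unknowns, independent, parameters)
        for eq in spec["equations"]
    ]
    conditions = [
        PointCondition(
            unknown=c["unknown"],
            derivative_order=int(c.get("order", 0)),
            abscissa=exact(c["at"]),
            value=exact(c["value"]),
        )
        for c in spec["conditions"]
    ]
    interval = tuple(spec.get("interval", (0, 1)))
    params = {k: (None if v is None else exact(v)) for k, v in parameters.items()}
    return ODESystemProblem(
        unknowns=tuple(unknowns),
        independent_variable=independent,
        residuals=tuple(residuals),
        conditions=tuple(conditions),
        parameters=params,
        domain_interval=interval,
    )


def homotopy_from_dict(
    spec: Mapping, problem: ODESystemProblem, control_parameter=None
) -> HomotopyConfig:
    """Homotopy operators from config strings (``L`` and ``u0`` per unknown)."""
    params = list(problem.parameters)
    L = {
        name: parse_expression(text, problem.unknowns, problem.independent_variable, params)
        for name, text in spec["L"].items()
    }
    u0 = {
        name: sp.sympify(text, locals={problem.independent_variable: problem.var,
                                       **{p: sp.Symbol(p) for p in params}})
        for name, text in spec["u0"].items()
    }
    embedding = spec.get("embedding", "classic")
    if control_parameter is None:
        control_parameter = HBAR if embedding == "hbar" else sp.S.One
    return HomotopyConfig(
        linear_operators=L,
        initial_approximations=u0,
        control_parameter=control_parameter,
        embedding=embedding,
    )


def ansatz_from_spec(spec) -> RationalAnsatz:
    """``{numerator: [...], denominator: [...]}`` or ``{even_odd: Q}``."""
    if isinstance(spec, RationalAnsatz):
        return spec
    if "even_odd" in spec:
        return RationalAnsatz.even_odd(int(spec["even_odd"]))
    return make_ansatz(spec["numerator"], spec.get("denominator", ()))


@dataclass
class RunConfig:
    """Everything one GHM run needs, validated."""

    problem: ODESystemProblem
    homotopy: HomotopyConfig
    ansatz: RationalAnsatz
    case_name: str | None = None
    mode: str = "exact"
    precision: int = 30
    hbar: sp.Expr | None = None          # fixed value (None: keep symbolic / classic)
    sweep_grid: tuple | None = None      # (lo, hi, step) exact values
    K: int = 500
    dt: float = 0.1
    tolerance: float = 1e-12
    interval: tuple | None = None
    output_dir: Path = Path("ghm-output")
    digits: int = 8                      # significant digits on rendered output

    def __post_init__(self):
        if self.sweep_grid is not None:
            lo, hi, step = (exact(v) for v in self.sweep_grid)
            if not (lo < hi and step > 0):
                raise ValueError("sweep grid needs lo < hi and step > 0")
            self.sweep_grid = (lo, hi, step)
        if self.hbar is not None:
            self.hbar = exact(self.hbar)
        self.output_dir = Path(self.output_dir)


def load_run_config(source) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file path or a mapping."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = dict(source)

    prob_spec = doc.get("problem", "smoking_spain")
    case_name = None
    if isinstance(prob_spec, str):
        case_name = CASE_ALIASES.get(prob_spec)
        if case_name is None:
            raise ValueError(
                f"unknown built-in problem {prob_spec!r}; available: "
                f"{sorted(set(CASE_ALIASES.values()))}"
            )
        cs = get_case_study(case_name)
        problem, homotopy = cs.build(**(doc.get("problem_args") or {}))
        ansatz = ansatz_from_spec(doc["ansatz"]) if "ansatz" in doc else cs.ansatz
    else:
        problem = problem_from_dict(prob_spec)
        if "homotopy" not in doc:
            raise ValueError("inline problems need a 'homotopy' section (L, u0)")
        ansatz = ansatz_from_spec(doc["ansatz"])
        homotopy = None  # built below once hbar handling is known

    hbar_doc = doc.get("hbar")
    sweep_grid = None
    hbar = None
    if isinstance(hbar_doc, Mapping):
        sweep_grid = (hbar_doc["lo"], hbar_doc["hi"], hbar_doc["step"])
    elif hbar_doc is not None:
        hbar = exact(hbar_doc)

    if homotopy is None:
        control = HBAR if (sweep_grid is not None or hbar is not None) else None
        homotopy = homotopy_from_dict(doc["homotopy"], problem, control_parameter=control)

    val = doc.get("validation", {}) or {}
    return RunConfig(
        problem=problem,
        homotopy=homotopy,
        ansatz=ansatz,
        case_name=case_name,
        mode=doc.get("mode", "exact"),
        precision=int(doc.get("precision", 30)),
        hbar=hbar,
        sweep_grid=sweep_grid,
        K=int(val.get("K", 500)),
        dt=float(val.get("dt", 0.1)),
        tolerance=float(val.get("tolerance", 1e-12)),
        interval=tuple(val["interval"]) if "interval" in val else None,
        output_dir=doc.get("output", "ghm-output"),
        digits=int(doc.get("digits", 8)),
    )
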