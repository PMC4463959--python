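"""Declarative nonlinear ODE problems and the built-in case studies.

A problem is a system of residual expressions (one per unknown, equal to
zero on solutions), a set of point conditions, exact-rational parameter
values, and a validation interval.  Three case studies ship built in:

``gelfand``
    The Gelfand/Bratu two-point boundary-value problem
    ``y'' + kappa*exp(y) = 0, y(0) = y(1) = 0`` — thermal ignition of a
    combustible gas — with the exponential optionally replaced by a Taylor
    polynomial to keep the cascade in polynomial form.

``heat_radiation``
    Lumped convective-radiative cooling
    ``theta' + theta + eps1*theta*theta' + eps2*theta^4 = 0, theta(0) = 1``,
    with the two radiation coefficients optionally left symbolic so the
    cascade solutions stay fully parametric.

``smoking_spain``
    A four-compartment model of the evolution of the smoking habit in Spain
    (never-smokers n, normal smokers s, excessive smokers c, ex-smokers e)
    with published transfer rates and 2000-era initial proportions; the
    total population is normalized, so n + s + c + e = 1 is conserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import sympy as sp
from sympy import Rational, S

__all__ = [
    "PointCondition",
    "ODESystemProblem",
    "truncate_nonlinearity",
    "gelfand_problem",
    "heat_radiation_problem",
    "smoking_model_problem",
    "SMOKING_RATES",
    "SMOKING_INITIAL",
    "apply_operator",
    "exact",
]


def exact(value) -> sp.Expr:
    """Coerce a numeric parameter to an exact rational (decimals stay exact).

    Symbols and sympy expressions pass through untouched, so parameters may
    remain symbolic.
    """
    if isinstance(value, sp.Expr):
        return value if not value.is_Float else Rational(str(value))
    if isinstance(value, str):
        return sp.sympify(value, rational=True)
    if isinstance(value, float):
        return Rational(Fraction(str(value)))
    return sp.Integer(value) if isinstance(value, int) else sp.sympify(value)


def apply_operator(op_expr: sp.Expr, func: sp.Expr, target: sp.Expr, x: sp.Symbol) -> sp.Expr:
    """Evaluate an operator expression written in ``func`` at a concrete ``target``."""
    reps = {}
    for d in op_expr.atoms(sp.Derivative):
        if d.expr == func:
            n = sum(int(c) for _, c in d.variable_count)
            reps[d] = sp.diff(target, x, n)
    reps[func] = target
    return sp.expand(op_expr.xreplace(reps))


@dataclass(frozen=True)
class PointCondition:
    """``d^k u / dx^k (abscissa) = value`` for one unknown."""

    unknown: str
    derivative_order: int
    abscissa: sp.Expr
    value: sp.Expr

    def __post_init__(self):
        object.__setattr__(self, "abscissa", exact(self.abscissa))
        object.__setattr__(self, "value", exact(self.value))
        if self.derivative_order < 0:
            raise ValueError("derivative order must be non-negative")


@dataclass(frozen=True)
class ODESystemProblem:
    """A first- or second-order nonlinear ODE system with point conditions.

    ``residuals[i]`` is an expression in ``Function(unknowns[i])(x)`` (and
    possibly the other unknowns), equal to zero on solutions.  Parameters
    appear as symbols in the residuals; their values (exact rationals, or
    ``None`` for deliberately symbolic parameters) live in ``parameters``.
    """

    unknowns: tuple
    independent_variable: str
    residuals: tuple
    conditions: tuple
    parameters: Mapping[str, sp.Expr | None] = field(default_factory=dict)
    domain_interval: tuple = (S.Zero, S.One)

    def __post_init__(self):
        object.__setattr__(self, "unknowns", tuple(self.unknowns))
        object.__setattr__(self, "residuals", tuple(sp.sympify(r) for r in self.residuals))
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(
            self,
            "parameters",
            {k: (None if v is None else exact(v)) for k, v in dict(self.parameters).items()},
        )
        object.__setattr__(
            self, "domain_interval", tuple(exact(v) for v in self.domain_interval)
        )
        self._check_wellposed()

    # -- structure ----------------------------------------------------------

    @property
    def var(self) -> sp.Symbol:
        return sp.Symbol(self.independent_variable)

    def func(self, name: str) -> sp.Expr:
        return sp.Function(name)(self.var)

    def derivative_order(self, name: str) -> int:
        u = self.func(name)
        order = 0
        for r in self.residuals:
            for d in r.atoms(sp.Derivative):
                if d.expr == u:
                    order = max(order, sum(int(c) for _, c in d.variable_count))
        return order

    def parameter_values(self) -> dict[sp.Symbol, sp.Expr]:
        return {
            sp.Symbol(k): v for k, v in self.parameters.items() if v is not None
        }

    def residuals_numeric(self) -> tuple:
        vals = self.parameter_values()
        return tuple(sp.expand(r.subs(vals)) for r in self.residuals)

    def conditions_for(self, name: str) -> tuple:
        return tuple(c for c in self.conditions if c.unknown == name)

    # -- invariants ---------------------------------------------------------

    def _check_wellposed(self):
        if len(self.residuals) != len(self.unknowns):
            raise ValueError(
                f"{len(self.unknowns)} unknowns but {len(self.residuals)} residuals"
            )
        lo, hi = self.domain_interval
        for c in self.conditions:
            if c.unknown not in self.unknowns:
                raise ValueError(f"condition references undeclared unknown {c.unknown!r}")
            if not (lo <= c.abscissa <= hi):
                raise ValueError(
                    f"condition abscissa {c.abscissa} outside interval [{lo}, {hi}]"
                )
        for name in self.unknowns:
            order = self.derivative_order(name)
            n_conds = len(self.conditions_for(name))
            if n_conds != order:
                raise ValueError(
                    f"unknown {name!r}: derivative order {order} but {n_conds} "
                    "conditions (well-posedness count)"
                )
            for c in self.conditions_for(name):
                if c.derivative_order >= order:
                    raise ValueError(
                        f"condition on {name!r} uses derivative order "
                        f"{c.derivative_order} >= ODE order {order}"
                    )


# ---------------------------------------------------------------------------
# polynomial truncation of non-polynomial nonlinearities
# ---------------------------------------------------------------------------


def truncate_nonlinearity(expr, about, center, n_terms: int) -> sp.Expr:
    """Taylor polynomial of ``expr`` in the unknown, with ``n_terms`` terms.

    ``about`` may be a symbol or its name; the result has degree
    ``n_terms - 1``.  Non-analytic expressions at the center are rejected.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be a positive integer")
    sym = sp.Symbol(about) if isinstance(about, str) else about
    expr = sp.sympify(expr)
    center = exact(center)
    try:
        poly = expr.series(sym, center, n_terms).removeO()
    except (sp.PoleError, NotImplementedError, ValueError) as err:
        raise ValueError(
            f"expression {expr} is not analytic in {sym} at {center}: {err}"
        ) from None
    poly = sp.expand(poly)
    if not poly.is_polynomial(sym):
        raise ValueError(
            f"expression {expr} is not analytic in {sym} at {center}: "
            f"its expansion {poly} is not polynomial"
        )
    return poly


# ---------------------------------------------------------------------------
# case-study builders
# ---------------------------------------------------------------------------


def gelfand_problem(kappa=1, taylor_terms: int | None = 4) -> ODESystemProblem:
    """Gelfand/Bratu BVP ``y'' + kappa*exp(y) = 0`` on [0, 1], y(0)=y(1)=0.

    ``taylor_terms`` truncates ``exp(y)`` to that many Taylor terms (the
    default cubic truncation, ``1 + y + y^2/2 + y^3/6``, is the one the
    reference cascade coefficients correspond to); ``None`` keeps the full
    exponential, which the closed-form cascade cannot digest but the
    numerical reference can.  Solutions exist only for ``kappa`` below the
    Bratu critical value (about 3.51); this is not enforced.
    """
    t = sp.Symbol("t")
    y = sp.Function("y")(t)
    kap = sp.Symbol("kappa")
    ysym = sp.Symbol("y")
    if taylor_terms is None:
        nonlin = sp.exp(ysym)
    else:
        nonlin = truncate_nonlinearity(sp.exp(ysym), ysym, 0, taylor_terms)
    residual = sp.Derivative(y, (t, 2)) + kap * nonlin.subs(ysym, y)
    return ODESystemProblem(
        unknowns=("y",),
        independent_variable="t",
        residuals=(residual,),
        conditions=(
            PointCondition("y", 0, 0, 0),
            PointCondition("y", 0, 1, 0),
        ),
        parameters={"kappa": None if isinstance(kappa, sp.Symbol) else exact(kappa)},
        domain_interval=(0, 1),
    )


def heat_radiation_problem(eps1=None, eps2=None, interval=(0, 5)) -> ODESystemProblem:
    """Lumped convective-radiative cooling IVP, ``theta(0) = 1``.

    ``eps1`` (Biot-like coupling of the temperature-dependent heat capacity)
    and ``eps2`` (radiation-to-convection ratio) may be numbers or ``None``
    to stay symbolic, keeping the cascade solutions parametric.
    """
    tau = sp.Symbol("tau")
    th = sp.Function("theta")(tau)
    e1, e2 = sp.symbols("epsilon_1 epsilon_2")
    residual = (
        sp.Derivative(th, tau) + th + e1 * th * sp.Derivative(th, tau) + e2 * th**4
    )
    return ODESystemProblem(
        unknowns=("theta",),
        independent_variable="tau",
        residuals=(residual,),
        conditions=(PointCondition("theta", 0, 0, 1),),
        parameters={
            "epsilon_1": None if eps1 is None else exact(eps1),
            "epsilon_2": None if eps2 is None else exact(eps2),
        },
        domain_interval=interval,
    )


#: published transfer rates for Spain (per year)
SMOKING_RATES = {
    "mu": "0.01",       # birth rate
    "rho": "0.0425",    # ex-smokers relapsing
    "beta": "0.0381",   # social-pressure transmission
    "alpha": "0.1244",  # excessive -> normal smoker
    "gamma": "0.1175",  # normal -> excessive smoker
    "lamda": "0.0498",  # normal smokers quitting
    "delta": "0.0498",  # excessive smokers quitting
}

#: initial proportions (n, s, c, e); they sum to exactly 1
SMOKING_INITIAL = {"n": "0.5045", "s": "0.2059", "c": "0.1559", "e": "0.1337"}


def smoking_model_problem(
    rates: Mapping | None = None, initial: Mapping | None = None
) -> ODESystemProblem:
    """Four-compartment smoking-habit model on [0, 50] years.

    Compartments: never-smokers ``n``, normal smokers ``s`` (< 20
    cigarettes/day), excessive smokers ``c``, ex-smokers ``e``; all
    proportions of a normalized constant population.  A warning is issued if
    the initial proportions do not sum to 1, since the structural
    conservation law n + s + c + e = 1 then fails.
    """
    rates = {**SMOKING_RATES, **(rates or {})}
    initial = {**SMOKING_INITIAL, **(initial or {})}
    extra = (set(rates) - set(SMOKING_RATES)) | (set(initial) - set(SMOKING_INITIAL))
    absent = {k for k, v in {**rates, **initial}.items() if v is None}
    if extra or absent:
        raise ValueError(
            "all seven rates and four initial proportions are required "
            f"(unknown: {sorted(extra)}, unset: {sorted(absent)})"
        )
    t = sp.Symbol("t")
    n, s, c, e = (sp.Function(u)(t) for u in "nsce")
    mu, rho, beta, alpha, gamma, lamda, delta = sp.symbols(
        "mu rho beta alpha gamma lamda delta"
    )
    D = lambda u: sp.Derivative(u, t)
    residuals = (
        D(n) - mu * (1 - n) + beta * n * (s + c),
        D(s) - beta * n * (s + c) - rho * e - alpha * c + (gamma + lamda + mu) * s,
        D(c) - gamma * s + (alpha + delta + mu) * c,
        D(e) - lamda * s - delta * c + (rho + mu) * e,
    )
    init_vals = {k: exact(v) for k, v in initial.items()}
    total = sum(init_vals.values())
    if abs(total - 1) > Rational(1, 10**6):
        warnings.warn(
            f"initial proportions sum to {total}, not 1: the conservation law "
            "n+s+c+e=1 will not hold",
            stacklevel=2,
        )
    return ODESystemProblem(
        unknowns=("n", "s", "c", "e"),
        independent_variable="t",
        residuals=residuals,
        conditions=tuple(
            PointCondition(u, 0, 0, init_vals[u]) for u in ("n", "s", "c", "e")
        ),
        parameters={k: exact(v) for k, v in rates.items()},
        domain_interval=(0, 50),
    )
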