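"""Closed-form solution of the cascade and assembly of the rational approximant.

The cascade is solved *composite-first*: the order-``k`` deformation equation
is linear in the composite ``g_k`` (e.g. ``w = -v0*v2`` turns
``-v0*v2'' - 2*v0'*v2' - v0''*v2`` into plain ``w''``), so each order is a
constant-coefficient linear ODE ``L(g_k) = rhs`` with right-hand side built
from already-solved composites.  Homogeneous point conditions at higher
orders are imposed on the composite, not on the individual ansatz
components — the recovered components may therefore be nonzero at the
condition abscissae, while the assembled approximant still satisfies every
condition exactly.

After the cascade is solved the triangular composite relations are inverted
(each order introduces exactly one new component, linearly, with coefficient
``1`` or ``+/- v0``), and the ``p -> 1`` limit assembles the rational
approximant: numerator = sum of numerator components, denominator = 1 + sum
of denominator components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import sympy as sp
from sympy import S

from .exppoly import ClosedFormError, ExpPoly, linear_operator_coeffs, solve_linear_ode
from .homotopy import (
    CascadeEquation,
    HomotopyConfig,
    RationalAnsatz,
    TaylorForm,
    build_homotopy,
    derive_cascade,
    taylor_form,
)
from .problems import ODESystemProblem

__all__ = [
    "CascadeSolution",
    "RationalApproximant",
    "solve_cascade",
    "recover_components",
    "assemble",
    "series_residual_check",
    "GHMResult",
    "run_ghm",
]


@dataclass
class CascadeSolution:
    """Solved composites ``g_0..g_T`` per unknown, as exact closed forms."""

    problem: ODESystemProblem
    config: HomotopyConfig
    composites: Mapping[str, Sequence[ExpPoly]]

    def expr(self, unknown: str, order: int) -> sp.Expr:
        return self.composites[unknown][order].to_expr()

    @property
    def truncation_order(self) -> int:
        return len(next(iter(self.composites.values()))) - 1


def _free_params(problem: ODESystemProblem, config: HomotopyConfig):
    params = set()
    for name, value in problem.parameters.items():
        if value is None:
            params.add(sp.Symbol(name))
    params |= config.control_parameter.free_symbols
    return tuple(sorted(params, key=str))


def solve_cascade(
    cascade: Sequence[CascadeEquation],
    problem: ODESystemProblem,
    config: HomotopyConfig,
    mode: str = "exact",
    precision: int = 30,
) -> CascadeSolution:
    """Solve the ordered cascade exactly, order by order.

    Each order's equation is rearranged as ``L(g_k) = rhs`` (the composite is
    the only order-``k`` quantity and enters only through the linear
    operator); the right-hand side is converted into the polynomial x
    exponential ring with the already-solved composites substituted, and the
    bespoke closed-form routine integrates it.  A right-hand side outside
    the ring raises :class:`~ghm.exppoly.ClosedFormError` naming the
    offending term — there is no silent numerical fallback.

    ``mode='floating'`` performs the same exact computation but renders the
    stored closed forms with ``precision`` significant digits (outputs are
    then rounded separately, typically to 8 digits).
    """
    if mode not in ("exact", "floating"):
        raise ValueError("mode must be 'exact' or 'floating'")
    x = problem.var
    params = _free_params(problem, config)
    values = problem.parameter_values()
    operators = {
        name: linear_operator_coeffs(
            sp.sympify(config.linear_operators[name]).subs(values),
            problem.func(name),
            x,
        )
        for name in problem.unknowns
    }
    env: dict = {}
    solved: dict[str, list[ExpPoly]] = {name: [] for name in problem.unknowns}
    for eq in sorted(cascade, key=lambda e: (e.order, list(problem.unknowns).index(e.unknown))):
        if len(solved[eq.unknown]) != eq.order:
            raise ValueError("cascade equations out of order or incomplete")
        rest = eq.expr.subs(eq.placeholder, 0).doit()
        rest = sp.expand(rest.subs(values))
        rhs = -ExpPoly.from_expr(rest, x, params, env=env)
        coeffs = operators[eq.unknown]
        conditions = [
            (d, a, sp.sympify(v).subs(values)) for d, a, v in eq.conditions
        ]
        g = solve_linear_ode(coeffs, rhs, conditions)
        # exact residual check: the solved composite satisfies its equation
        residual = sum(
            (g.diff(k).scale(a) for k, a in enumerate(coeffs)),
            ExpPoly.zero(x, params),
        ) - rhs
        if not residual.is_zero:
            raise ClosedFormError(
                f"order-{eq.order} solution for {eq.unknown} leaves residual "
                f"{residual.to_expr()}"
            )
        env[eq.placeholder] = g
        solved[eq.unknown].append(g)
    if mode == "floating":
        solved = {
            name: [_render_float(g, precision) for g in comps]
            for name, comps in solved.items()
        }
    return CascadeSolution(problem=problem, config=config, composites=solved)


def _render_float(g: ExpPoly, precision: int) -> ExpPoly:
    terms = {
        mu: {d: sp.nsimplify(sp.N(c, precision), rational=True) for d, c in poly.items()}
        for mu, poly in g.terms.items()
    }
    return ExpPoly(terms, g.x, g.params)


def recover_components(
    taylor: TaylorForm, composites: Sequence[ExpPoly]
) -> dict[int, ExpPoly]:
    """Invert the triangular composite relations for one unknown.

    At order ``k`` the composite is linear in the single new component with
    coefficient ``1`` (numerator power) or ``-v0 * (..)`` (denominator
    power); the relation is divided through exactly.  Removable singularities
    cancel: for a boundary-value problem the composite shares the endpoint
    zeros of ``v0``'s factors, and the quotient is returned in cancelled
    (polynomial) form.
    """
    T = taylor.truncation_order
    if len(composites) != T + 1:
        raise ValueError(f"need {T + 1} solved composites, got {len(composites)}")
    x, params = composites[0].x, composites[0].params
    env: dict = {}
    out: dict[int, ExpPoly] = {}
    for k in range(T + 1):
        sym = taylor.component_symbols[k]
        gk = taylor.composites[k]
        coeff_expr = sp.expand(sp.diff(gk, sym))
        rest_expr = sp.expand(gk.subs(sym, 0))
        rest = ExpPoly.from_expr(rest_expr, x, params, env=env)
        numerator = composites[k] - rest
        if coeff_expr == 1:
            comp = numerator
        else:
            coeff = ExpPoly.from_expr(coeff_expr, x, params, env=env)
            if coeff.is_zero:
                raise ClosedFormError(
                    f"ansatz unusable: the coefficient of component {sym} vanishes "
                    "identically at its first appearance"
                )
            comp = numerator.div(coeff)
        env[sym] = comp
        out[k] = comp
    return out


@dataclass
class RationalApproximant:
    """Assembled ``p -> 1`` limit of the rational ansatz for one unknown.

    ``numerator`` and ``denominator`` are closed-form expressions in the
    independent variable (and any still-symbolic parameters, e.g. the
    convergence-control parameter); the quotient satisfies the problem's
    point conditions exactly wherever the denominator is nonzero.
    """

    unknown: str
    numerator: sp.Expr
    denominator: sp.Expr
    var: sp.Symbol
    metadata: dict = field(default_factory=dict)

    @property
    def expr(self) -> sp.Expr:
        return self.numerator / self.denominator

    @property
    def free_parameters(self) -> set:
        return (self.numerator.free_symbols | self.denominator.free_symbols) - {self.var}

    def subs(self, mapping: Mapping) -> "RationalApproximant":
        mapping = {sp.Symbol(k) if isinstance(k, str) else k: v for k, v in mapping.items()}
        return RationalApproximant(
            unknown=self.unknown,
            numerator=sp.expand(self.numerator.subs(mapping)),
            denominator=sp.expand(self.denominator.subs(mapping)),
            var=self.var,
            metadata={**self.metadata, "substituted": {str(k): v for k, v in mapping.items()}},
        )

    def normalized(self) -> "RationalApproximant":
        """Scale a polynomial quotient so the denominator's constant term is 1."""
        c0 = self.denominator.coeff(self.var, 0)
        if c0 == 0:
            raise ZeroDivisionError("denominator has no constant term")
        return RationalApproximant(
            unknown=self.unknown,
            numerator=sp.expand(self.numerator / c0),
            denominator=sp.expand(self.denominator / c0),
            var=self.var,
            metadata=dict(self.metadata),
        )

    def polynomial_coefficients(self) -> tuple[dict[int, sp.Expr], dict[int, sp.Expr]]:
        """``{degree: coefficient}`` for numerator and denominator polynomials."""
        out = []
        for part in (self.numerator, self.denominator):
            poly = sp.Poly(part, self.var)
            out.append({int(m[0]): c for m, c in zip(poly.monoms(), poly.coeffs())})
        return tuple(out)

    def lambdified(self, extra_symbols: Sequence = ()):
        args = (self.var, *extra_symbols)
        fn = sp.lambdify(args, self.numerator, "numpy")
        fd = sp.lambdify(args, self.denominator, "numpy")

        def f(*vals):
            import numpy as np

            t = np.asarray(vals[0], dtype=float)
            return fn(t, *vals[1:]) / fd(t, *vals[1:])

        return f

    def __call__(self, tval, **param_values):
        subs = {self.var: sp.sympify(tval)}
        subs.update({sp.Symbol(k): sp.sympify(v) for k, v in param_values.items()})
        return (self.numerator.subs(subs)) / (self.denominator.subs(subs))


def assemble(
    ansatz: RationalAnsatz,
    components: Mapping[int, ExpPoly],
    unknown: str = "u",
    problem: ODESystemProblem | None = None,
    metadata: dict | None = None,
) -> RationalApproximant:
    """Set ``p = 1``: sum numerator and denominator components into a quotient."""
    some = next(iter(components.values()))
    x, params = some.x, some.params
    num = ExpPoly.zero(x, params)
    for w in ansatz.numerator_powers:
        num = num + components[w]
    den = ExpPoly.constant(S.One, x, params)
    for m in ansatz.denominator_powers:
        den = den + components[m]
    approx = RationalApproximant(
        unknown=unknown,
        numerator=num.to_expr(),
        denominator=den.to_expr(),
        var=x,
        metadata={"ansatz": ansatz, **(metadata or {})},
    )
    if problem is not None:
        for cond in problem.conditions_for(unknown):
            val = sp.simplify(approx.denominator.subs(x, cond.abscissa))
            if val == 0:
                raise ZeroDivisionError(
                    f"assembled denominator for {unknown} vanishes at the condition "
                    f"abscissa {cond.abscissa}"
                )
    return approx


def series_residual_check(
    taylor: TaylorForm,
    components: Mapping[int, ExpPoly],
    composites: Sequence[ExpPoly],
) -> int | None:
    """Re-expand the recovered components through the composite relations.

    Returns the first ``p``-order at which the re-expanded coefficient
    disagrees with the solved composite, or ``None`` when the round trip is
    exact (the expected outcome).
    """
    some = next(iter(components.values()))
    x, params = some.x, some.params
    env = {taylor.component_symbols[j]: components[j] for j in components}
    for k in range(taylor.truncation_order + 1):
        re_expanded = ExpPoly.from_expr(taylor.composites[k], x, params, env=env)
        if not (re_expanded - composites[k]).is_zero:
            return k
    return None


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------


@dataclass
class GHMResult:
    """Everything produced by one GHM run, exact and inspectable."""

    problem: ODESystemProblem
    config: HomotopyConfig
    ansatz: RationalAnsatz
    taylors: Mapping[str, TaylorForm]
    cascade: Sequence[CascadeEquation]
    solution: CascadeSolution
    components: Mapping[str, Mapping[int, ExpPoly]]
    approximants: Mapping[str, RationalApproximant]

    def approximant(self, unknown: str | None = None) -> RationalApproximant:
        if unknown is None:
            (unknown,) = self.problem.unknowns
        return self.approximants[unknown]

    def substitute(self, mapping: Mapping) -> dict[str, RationalApproximant]:
        return {name: a.subs(mapping) for name, a in self.approximants.items()}

    def roundtrip_mismatch(self) -> dict[str, int | None]:
        return {
            name: series_residual_check(
                self.taylors[name],
                self.components[name],
                self.solution.composites[name],
            )
            for name in self.problem.unknowns
        }


def run_ghm(
    problem: ODESystemProblem,
    config: HomotopyConfig,
    ansatz: RationalAnsatz,
    mode: str = "exact",
    precision: int = 30,
) -> GHMResult:
    """Full pipeline: homotopy -> cascade -> closed-form solve -> assembly."""
    taylors = {
        name: taylor_form(ansatz, symbol_base=f"_{name}_v")
        for name in problem.unknowns
    }
    homotopy = build_homotopy(problem, config)
    cascade = derive_cascade(homotopy, taylors, problem)
    solution = solve_cascade(cascade, problem, config, mode=mode, precision=precision)
    components = {
        name: recover_components(taylors[name], solution.composites[name])
        for name in problem.unknowns
    }
    approximants = {
        name: assemble(
            ansatz,
            components[name],
            unknown=name,
            problem=problem,
            metadata={
                "order": ansatz.truncation_order,
                "mode": mode,
                "control_parameter": config.control_parameter,
            },
        )
        for name in problem.unknowns
    }
    return GHMResult(
        problem=problem,
        config=config,
        ansatz=ansatz,
        taylors=taylors,
        cascade=cascade,
        solution=solution,
        components=components,
        approximants=approximants,
    )
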