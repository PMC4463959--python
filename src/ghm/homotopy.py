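"""Homotopy embedding, rational ansatz, Taylor composites, and the cascade.

The generalized homotopy method (GHM) embeds a nonlinear ODE residual
``L(u) + N(u) - f = 0`` into the one-parameter family

    H(v, p) = (1 - p) [L(v) - L(u0)] + hbar * p * (full residual at v) = 0,

``p in [0, 1]``, where ``u0`` is an initial approximation satisfying the
problem's point conditions, and ``hbar`` is a convergence-control parameter
(``hbar = 1`` recovers the classic embedding).  At ``p = 0`` the family is a
trivial linear problem; at ``p = 1`` (classic form) it is the original
equation.

Instead of the usual power-series ansatz ``v = sum v_k p^k``, GHM posits a
*rational* ansatz: a quotient of two polynomials in ``p`` whose coefficient
functions are all unknown,

    v = (sum_{w in W} v_w p^w) / (1 + sum_{m in M} v_m p^m),

with disjoint numerator/denominator power sets (repeating a power on both
sides breaks the triangular structure, so it is rejected).  Expanding the
quotient as a Taylor series in ``p`` gives composite coefficients
``g_k(v_0, .., v_k)``; substituting the series into ``H`` and equating
``p``-powers to zero yields a cascade of *linear* ODEs, one per composite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import sympy as sp
from sympy import S

from .problems import ODESystemProblem, PointCondition, apply_operator
from .exppoly import ClosedFormError

__all__ = [
    "RationalAnsatz",
    "make_ansatz",
    "TaylorForm",
    "taylor_form",
    "HomotopyConfig",
    "build_homotopy",
    "CascadeEquation",
    "derive_cascade",
    "P",
]

#: the homotopy (embedding) parameter
P = sp.Symbol("p")


# ---------------------------------------------------------------------------
# rational ansatz
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RationalAnsatz:
    """Disjoint numerator/denominator ``p``-power sets of the rational ansatz.

    ``numerator_powers`` must contain 0 (the order-0 term seeds the cascade)
    and be disjoint from ``denominator_powers``; the denominator's constant
    term is fixed to 1 and is not an unknown.
    """

    numerator_powers: frozenset
    denominator_powers: frozenset

    def __post_init__(self):
        num = frozenset(int(w) for w in self.numerator_powers)
        den = frozenset(int(m) for m in self.denominator_powers)
        object.__setattr__(self, "numerator_powers", num)
        object.__setattr__(self, "denominator_powers", den)
        if any(w < 0 for w in num) or any(m <= 0 for m in den):
            raise ValueError("numerator powers must be >= 0 and denominator powers >= 1")
        if 0 not in num:
            raise ValueError("the numerator must contain the p^0 term")
        if num & den:
            raise ValueError(
                "powers repeated in numerator and denominator break the method; "
                f"overlap: {sorted(num & den)}"
            )

    @property
    def truncation_order(self) -> int:
        """One cascade equation per unknown coefficient function."""
        return len(self.numerator_powers) + len(self.denominator_powers) - 1

    @property
    def n_functions(self) -> int:
        return len(self.numerator_powers) + len(self.denominator_powers)

    @property
    def is_series(self) -> bool:
        """True for the degenerate (denominator-free) plain-HPM ansatz."""
        return not self.denominator_powers

    @classmethod
    def contiguous(cls, W: int, M: int | None = None) -> "RationalAnsatz":
        """Numerator powers ``0..W`` over denominator powers ``W+1..M``."""
        if M is None:
            return cls(frozenset(range(W + 1)), frozenset())
        if not M > W >= 0:
            raise ValueError("need M > W >= 0")
        return cls(frozenset(range(W + 1)), frozenset(range(W + 1, M + 1)))

    @classmethod
    def even_odd(cls, Q: int) -> "RationalAnsatz":
        """Even powers ``0,2,..,2Q`` over odd powers ``1,3,..,2Q-1``."""
        if Q < 1:
            raise ValueError("need Q >= 1")
        return cls(
            frozenset(range(0, 2 * Q + 1, 2)),
            frozenset(range(1, 2 * Q, 2)),
        )

    def describe(self) -> str:
        num = "+".join(f"v{w}*p^{w}" for w in sorted(self.numerator_powers))
        den = "+".join(f"v{m}*p^{m}" for m in sorted(self.denominator_powers))
        return f"({num}) / (1+{den})" if den else num


def make_ansatz(numerator_powers, denominator_powers=()) -> RationalAnsatz:
    """Validated rational ansatz from explicit power sets."""
    return RationalAnsatz(frozenset(numerator_powers), frozenset(denominator_powers))


# ---------------------------------------------------------------------------
# Taylor composites
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaylorForm:
    """Exact ``p``-power coefficients of the expanded rational ansatz.

    ``composites[k]`` is the polynomial ``g_k(v_0, .., v_k)`` in the component
    symbols; ``component_symbols[j]`` is the symbol standing for the
    coefficient function attached to ``p^j`` (numerator or denominator side
    according to the ansatz).
    """

    ansatz: RationalAnsatz
    component_symbols: tuple
    composites: tuple

    @property
    def truncation_order(self) -> int:
        return self.ansatz.truncation_order

    def new_component(self, order: int) -> sp.Symbol:
        """The component symbol first appearing in composite ``order``."""
        return self.component_symbols[order]


def taylor_form(ansatz: RationalAnsatz, symbol_base: str = "v") -> TaylorForm:
    """Expand ``num(p)/den(p)`` as a Taylor series in ``p``, exactly.

    The expansion is carried to truncation order ``n_functions - 1`` so the
    cascade has exactly one equation per unknown coefficient function; the
    union of the power sets must therefore cover ``0..T`` without gaps.
    """
    T = ansatz.truncation_order
    covered = ansatz.numerator_powers | ansatz.denominator_powers
    if covered != set(range(T + 1)):
        raise ValueError(
            "ansatz power sets must jointly cover 0..truncation_order "
            f"(got {sorted(covered)}, need 0..{T}): unknown count would not "
            "match the number of cascade equations"
        )
    syms = tuple(sp.Symbol(f"{symbol_base}{j}") for j in range(T + 1))
    num = {w: syms[w] for w in ansatz.numerator_powers}
    den = {m: syms[m] for m in ansatz.denominator_powers}

    # inverse of (1 + sum V_m p^m) as a truncated p-series, by recursion
    inv = {0: S.One}
    for k in range(1, T + 1):
        inv[k] = sp.expand(-sum(den[m] * inv[k - m] for m in den if m <= k))
    composites = []
    for k in range(T + 1):
        g = sp.expand(sum(num[w] * inv[k - w] for w in num if w <= k))
        composites.append(g)
    tf = TaylorForm(ansatz, syms, tuple(composites))
    # sanity: g0 = v0 and each order introduces exactly its own new symbol
    assert composites[0] == syms[0]
    for k in range(1, T + 1):
        assert syms[k] in composites[k].free_symbols, "missing new component"
        assert not any(syms[j] in composites[k].free_symbols for j in range(k + 1, T + 1))
    return tf


# ---------------------------------------------------------------------------
# homotopy embedding
# ---------------------------------------------------------------------------


@dataclass
class HomotopyConfig:
    """Linear operator, initial approximation, and control parameter.

    ``linear_operators[name]`` is an expression in ``Function(name)(x)`` and
    its derivatives, linear with constant coefficients (e.g. ``u'' `` for a
    second-order problem, ``u' + u`` for exponential decay).
    ``initial_approximations[name]`` is an expression in the independent
    variable; it must satisfy every point condition of the problem exactly.
    ``embedding`` selects the classic form (control parameter fixed at 1) or
    the hbar-weighted form where ``control_parameter`` multiplies the
    ``p``-weighted full-residual bracket.
    """

    linear_operators: Mapping[str, sp.Expr]
    initial_approximations: Mapping[str, sp.Expr]
    control_parameter: sp.Expr = S.One
    embedding: str = "classic"

    def __post_init__(self):
        if self.embedding not in ("classic", "hbar"):
            raise ValueError("embedding must be 'classic' or 'hbar'")
        self.linear_operators = {k: sp.sympify(v) for k, v in self.linear_operators.items()}
        self.initial_approximations = {
            k: sp.sympify(v) for k, v in self.initial_approximations.items()
        }
        self.control_parameter = sp.sympify(self.control_parameter)

    @property
    def hbar(self) -> sp.Expr:
        return self.control_parameter if self.embedding == "hbar" else S.One

    def validate(self, problem: ODESystemProblem) -> None:
        """Check u0 against the point conditions and L for linearity."""
        x = problem.var
        for cond in problem.conditions:
            u0 = self.initial_approximations[cond.unknown]
            got = sp.simplify(
                sp.diff(u0, x, cond.derivative_order).subs(x, cond.abscissa) - cond.value
            )
            got = sp.simplify(got.subs(problem.parameter_values()))
            if got != 0:
                raise ValueError(
                    f"initial approximation for {cond.unknown} violates the condition "
                    f"{cond}: residual {got}"
                )
        # linearity spot check: L(a*f + b*g) == a*L(f) + b*L(g)
        f, g = sp.Function("_lin_f"), sp.Function("_lin_g")
        a, b = sp.symbols("_lin_a _lin_b")
        for name, L in self.linear_operators.items():
            u = sp.Function(name)(x)
            combo = apply_operator(L, u, a * f(x) + b * g(x), x)
            split = a * apply_operator(L, u, f(x), x) + b * apply_operator(L, u, g(x), x)
            if sp.simplify(sp.expand(combo - split).doit()) != 0:
                raise ValueError(f"operator for {name} is not linear: {L}")


def build_homotopy(
    problem: ODESystemProblem, config: HomotopyConfig
) -> dict[str, sp.Expr]:
    """Per-unknown homotopy residual ``H_i(v, p)``.

    Returns expressions in the problem's unknown functions and ``p``:
    ``(1-p)*(L(v_i) - L(u0_i)) + hbar*p*(residual_i)``.  At ``p = 0`` each
    reduces to ``L(v_i) - L(u0_i)``; in the classic embedding, at ``p = 1``
    each reduces to the original residual.
    """
    config.validate(problem)
    x = problem.var
    hbar = config.hbar
    out = {}
    for name, residual in zip(problem.unknowns, problem.residuals):
        u = problem.func(name)
        L = config.linear_operators[name]
        u0 = config.initial_approximations[name]
        L_of_u0 = apply_operator(L, u, u0, x)
        out[name] = sp.expand((1 - P) * (L - L_of_u0) + hbar * P * residual)
    return out


# ---------------------------------------------------------------------------
# cascade derivation
# ---------------------------------------------------------------------------


@dataclass
class CascadeEquation:
    """One linear deformation equation: the ``p^order`` coefficient of H.

    ``placeholder`` is the applied function standing for the composite
    ``g_order`` of ``unknown``; the equation is linear in it, and only
    lower-order composites (already solved) appear otherwise.  Order 0
    carries the problem's own point conditions, higher orders carry the
    homogeneous conditions at the same abscissae — imposed on the composite,
    not on the individual ansatz components.
    """

    unknown: str
    order: int
    placeholder: sp.Expr
    expr: sp.Expr
    conditions: tuple  # (derivative_order, abscissa, value)

    def is_linear_in_unknown(self, x: sp.Symbol) -> bool:
        """Second derivative of the equation w.r.t. the composite vanishes."""
        t = sp.Dummy("t_lin")
        probe = self.expr.subs(self.placeholder, t * self.placeholder).doit()
        return sp.expand(sp.diff(probe, t, 2)) == 0


def _placeholders(problem: ODESystemProblem, T: int) -> dict[str, list[sp.Expr]]:
    x = problem.var
    return {
        name: [sp.Function(f"{name}{k}")(x) for k in range(T + 1)]
        for name in problem.unknowns
    }


def derive_cascade(
    homotopy: Mapping[str, sp.Expr],
    taylors: Mapping[str, TaylorForm],
    problem: ODESystemProblem,
) -> list[CascadeEquation]:
    """Substitute the Taylor form into H, expand in ``p``, equate coefficients.

    Returns the flat list of cascade equations ordered by ``p``-power (and,
    within an order, by the problem's unknown ordering).  All unknowns must
    use ansatze of the same truncation order (one equation per unknown per
    order).
    """
    orders = {name: tf.truncation_order for name, tf in taylors.items()}
    if set(orders) != set(problem.unknowns):
        raise ValueError("need one Taylor form per unknown")
    if len(set(orders.values())) != 1:
        raise ValueError(f"mismatched truncation orders across unknowns: {orders}")
    T = next(iter(orders.values()))
    x = problem.var
    G = _placeholders(problem, T)
    series = {
        problem.func(name): sum(G[name][k] * P**k for k in range(T + 1))
        for name in problem.unknowns
    }
    by_unknown = {c.unknown: [] for c in problem.conditions}
    for c in problem.conditions:
        by_unknown.setdefault(c.unknown, []).append(c)

    equations: list[CascadeEquation] = []
    per_unknown_coeffs = {}
    for name in problem.unknowns:
        h = homotopy[name].subs(series).doit()
        h = sp.expand(h)
        per_unknown_coeffs[name] = [h.coeff(P, k) for k in range(T + 1)]
    for k in range(T + 1):
        for name in problem.unknowns:
            expr = per_unknown_coeffs[name][k]
            conds = []
            for c in by_unknown.get(name, []):
                value = c.value if k == 0 else S.Zero
                conds.append((c.derivative_order, c.abscissa, value))
            equations.append(
                CascadeEquation(
                    unknown=name,
                    order=k,
                    placeholder=G[name][k],
                    expr=expr,
                    conditions=tuple(conds),
                )
            )
    return equations
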