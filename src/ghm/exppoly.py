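"""Exact closed-form arithmetic over the ring of polynomial x exponential functions.

Every right-hand side met while solving the cascade of linear deformation
equations for the built-in case studies lives in the ring

    R = { sum_mu  exp(mu*x) * P_mu(x) },

where ``mu`` ranges over rational numbers and each ``P_mu`` is a polynomial in
``x`` whose coefficients are rational numbers or polynomials in declared
symbolic parameters (e.g. the convergence-control parameter, or the two
radiation coefficients of the cooling problem).  The ring is closed under
addition, multiplication, differentiation, antidifferentiation, and under
solving constant-coefficient linear ODEs ``sum_k a_k g^(k) = rhs`` with
rational ``a_k`` — which is exactly what the cascade requires.

:class:`ExpPoly` implements that ring, and :func:`solve_linear_ode` the
closed-form solver, including the resonant case (forcing proportional to a
homogeneous solution) via the standard ``x^m * exp(mu*x)`` particular form.

A deliberately restricted bespoke routine is used instead of a general ODE
black box: within the ring it is exact, deterministic and fast even at
truncation order twelve, and anything outside the ring is rejected loudly
(:class:`ClosedFormError`) rather than silently approximated.
"""

from __future__ import annotations

from typing import Callable, Iterable, Mapping, Sequence

import sympy as sp
from sympy import Rational, S

__all__ = ["ExpPoly", "ClosedFormError", "solve_linear_ode", "linear_operator_coeffs"]


class ClosedFormError(ValueError):
    """Raised when an expression or equation leaves the polynomial x exponential ring."""


def _as_rational(value) -> Rational:
    v = sp.nsimplify(sp.sympify(value), rational=True)
    if not v.is_Rational:
        raise ClosedFormError(f"expected a rational number, got {value!r}")
    return v


class ExpPoly:
    """An element ``sum_mu exp(mu*x) * sum_d c_{mu,d} x^d`` of the closed-form ring.

    Parameters
    ----------
    terms
        Mapping ``exponent -> {degree -> coefficient}``; exponents are exact
        rationals, degrees non-negative integers, coefficients sympy
        expressions in ``params`` only.
    x
        The independent variable.
    params
        Symbols allowed to appear in coefficients (everything else is
        rejected, which catches malformed input early).
    """

    __slots__ = ("x", "params", "terms")

    def __init__(self, terms: Mapping, x: sp.Symbol, params: Sequence[sp.Symbol] = ()):
        self.x = x
        self.params = tuple(params)
        clean: dict[Rational, dict[int, sp.Expr]] = {}
        for mu, poly in terms.items():
            mu = _as_rational(mu)
            dest = clean.setdefault(mu, {})
            for deg, coeff in poly.items():
                coeff = sp.expand(sp.sympify(coeff))
                if coeff == 0:
                    continue
                dest[int(deg)] = sp.expand(dest.get(int(deg), S.Zero) + coeff)
                if dest[int(deg)] == 0:
                    del dest[int(deg)]
            if not dest:
                del clean[mu]
        self.terms = clean

    # -- constructors -------------------------------------------------------

    @classmethod
    def zero(cls, x, params=()):
        return cls({}, x, params)

    @classmethod
    def constant(cls, value, x, params=()):
        return cls({S.Zero: {0: value}}, x, params)

    @classmethod
    def monomial(cls, coeff, degree, exponent, x, params=()):
        return cls({exponent: {degree: coeff}}, x, params)

    @classmethod
    def from_expr(cls, expr, x, params=(), env: Mapping | None = None) -> "ExpPoly":
        """Parse a sympy expression into the ring.

        ``env`` maps sympy atoms (typically applied ``Function`` instances
        standing for already-solved cascade components) to :class:`ExpPoly`
        values; their derivatives are resolved through :meth:`diff`.
        """
        env = env or {}
        params = tuple(params)
        pset = set(params)

        def rec(e) -> "ExpPoly":
            if e in env:
                val = env[e]
                return val if isinstance(val, ExpPoly) else rec(sp.sympify(val))
            if e == x:
                return cls.monomial(S.One, 1, S.Zero, x, params)
            if e.is_Number:
                return cls.constant(_as_rational(e), x, params)
            if e.is_Symbol:
                if e in pset:
                    return cls.constant(e, x, params)
                raise ClosedFormError(f"symbol {e} is neither the variable nor a declared parameter")
            if isinstance(e, sp.Derivative):
                base = e.expr
                if base in env:
                    val = env[base]
                    n = sum(int(c) for _, c in e.variable_count)
                    if not all(v == x for v, _ in e.variable_count):
                        raise ClosedFormError(f"derivative in a foreign variable: {e}")
                    return val.diff(n) if isinstance(val, ExpPoly) else rec(sp.sympify(val).diff(x, n))
                raise ClosedFormError(f"unresolved derivative {e}")
            if isinstance(e, sp.exp):
                arg = sp.expand(e.args[0])
                mu = arg.coeff(x, 1)
                rest = sp.expand(arg - mu * x)
                if rest != 0 or not mu.is_Rational:
                    raise ClosedFormError(f"exponential outside the ring: {e}")
                return cls.monomial(S.One, 0, mu, x, params)
            if isinstance(e, sp.Add):
                out = cls.zero(x, params)
                for a in e.args:
                    out = out + rec(a)
                return out
            if isinstance(e, sp.Mul):
                out = cls.constant(S.One, x, params)
                for a in e.args:
                    out = out * rec(a)
                return out
            if isinstance(e, sp.Pow):
                base, ex = e.args
                if ex.is_Integer and ex >= 0:
                    return rec(base) ** int(ex)
                # rational powers of pure exponentials stay in the ring
                if isinstance(base, sp.exp) and ex.is_Rational:
                    return rec(sp.exp(sp.expand(base.args[0] * ex)))
                raise ClosedFormError(f"power outside the ring: {e}")
            raise ClosedFormError(f"term outside the polynomial x exponential ring: {e}")

        return rec(sp.expand(sp.sympify(expr)))

    # -- ring operations ----------------------------------------------------

    def _compat(self, other) -> "ExpPoly":
        if not isinstance(other, ExpPoly):
            return ExpPoly.constant(other, self.x, self.params)
        if other.x != self.x:
            raise ClosedFormError("mixed independent variables")
        return other

    def __add__(self, other):
        other = self._compat(other)
        terms: dict = {mu: dict(p) for mu, p in self.terms.items()}
        for mu, poly in other.terms.items():
            dest = terms.setdefault(mu, {})
            for d, c in poly.items():
                dest[d] = dest.get(d, S.Zero) + c
        return ExpPoly(terms, self.x, self.params)

    __radd__ = __add__

    def __neg__(self):
        return ExpPoly(
            {mu: {d: -c for d, c in p.items()} for mu, p in self.terms.items()},
            self.x,
            self.params,
        )

    def __sub__(self, other):
        return self + (-self._compat(other))

    def __rsub__(self, other):
        return self._compat(other) + (-self)

    def __mul__(self, other):
        other = self._compat(other)
        terms: dict = {}
        for mu1, p1 in self.terms.items():
            for mu2, p2 in other.terms.items():
                dest = terms.setdefault(mu1 + mu2, {})
                for d1, c1 in p1.items():
                    for d2, c2 in p2.items():
                        d = d1 + d2
                        dest[d] = dest.get(d, S.Zero) + sp.expand(c1 * c2)
        return ExpPoly(terms, self.x, self.params)

    __rmul__ = __mul__

    def __pow__(self, n: int):
        if not (isinstance(n, int) and n >= 0):
            raise ClosedFormError("only non-negative integer powers are supported")
        out = ExpPoly.constant(S.One, self.x, self.params)
        for _ in range(n):
            out = out * self
        return out

    def scale(self, c):
        return ExpPoly(
            {mu: {d: co * c for d, co in p.items()} for mu, p in self.terms.items()},
            self.x,
            self.params,
        )

    # -- calculus -----------------------------------------------------------

    def diff(self, n: int = 1) -> "ExpPoly":
        out = self
        for _ in range(n):
            terms: dict = {}
            for mu, poly in out.terms.items():
                dest = terms.setdefault(mu, {})
                for d, c in poly.items():
                    if mu != 0:
                        dest[d] = dest.get(d, S.Zero) + mu * c
                    if d > 0:
                        dest[d - 1] = dest.get(d - 1, S.Zero) + d * c
            out = ExpPoly(terms, self.x, self.params)
        return out

    def integrate(self) -> "ExpPoly":
        """Antiderivative with zero integration constant (exact, term by term)."""
        terms: dict = {}
        for mu, poly in self.terms.items():
            dest = terms.setdefault(mu, {})
            if mu == 0:
                for d, c in poly.items():
                    dest[d + 1] = dest.get(d + 1, S.Zero) + c / Rational(d + 1)
            else:
                # int x^d e^{mu x} = e^{mu x} sum_{j<=d} (-1)^(d-j) d!/(j! mu^(d-j+1)) x^j
                for d, c in poly.items():
                    fact = S.One / mu
                    dest[d] = dest.get(d, S.Zero) + c * fact
                    for j in range(d - 1, -1, -1):
                        fact = -fact * (j + 1) / mu
                        dest[j] = dest.get(j, S.Zero) + c * fact
        return ExpPoly(terms, self.x, self.params)

    # -- queries ------------------------------------------------------------

    @property
    def is_zero(self) -> bool:
        return not self.terms

    @property
    def is_polynomial(self) -> bool:
        return all(mu == 0 for mu in self.terms)

    def poly_coeffs(self) -> dict[int, sp.Expr]:
        """Coefficients {degree: coeff} when the element is a pure polynomial."""
        if not self.is_polynomial:
            raise ClosedFormError("element has exponential parts")
        return dict(self.terms.get(S.Zero, {}))

    def eval(self, point) -> sp.Expr:
        point = sp.sympify(point)
        total = S.Zero
        for mu, poly in self.terms.items():
            pval = sum(c * point**d for d, c in poly.items())
            total += sp.exp(mu * point) * pval
        return sp.expand(total)

    def to_expr(self) -> sp.Expr:
        total = S.Zero
        for mu, poly in self.terms.items():
            pval = sum(c * self.x**d for d, c in poly.items())
            total += sp.exp(mu * self.x) * pval
        return total

    def subs_params(self, mapping: Mapping) -> "ExpPoly":
        new_params = tuple(p for p in self.params if p not in mapping)
        return ExpPoly(
            {
                mu: {d: sp.expand(c.subs(mapping)) for d, c in poly.items()}
                for mu, poly in self.terms.items()
            },
            self.x,
            new_params,
        )

    def div(self, other: "ExpPoly") -> "ExpPoly":
        """Exact division; the divisor must be a single-exponential term.

        Used when inverting the triangular composite relations, e.g.
        ``v2 = -g2 / v0``.  Division is exact in the ring or fails loudly —
        removable factors (the divisor's polynomial part sharing zeros with
        every dividend component) cancel exactly.
        """
        other = self._compat(other)
        if len(other.terms) != 1:
            raise ClosedFormError("division only by single-exponential-term elements")
        (mu0, qpoly), = other.terms.items()
        q_expr = sum(c * self.x**d for d, c in qpoly.items())
        terms: dict = {}
        for mu, poly in self.terms.items():
            p_expr = sum(c * self.x**d for d, c in poly.items())
            quot, rem = sp.div(p_expr, q_expr, self.x)
            if sp.simplify(rem) != 0:
                raise ClosedFormError("inexact polynomial division in component recovery")
            quot = sp.expand(quot)
            dest = terms.setdefault(mu - mu0, {})
            qq = sp.Poly(quot, self.x) if quot != 0 else None
            if qq is not None:
                for (d,), c in qq.terms():
                    dest[d] = dest.get(d, S.Zero) + c
        return ExpPoly(terms, self.x, self.params)

    def __repr__(self):
        return f"ExpPoly({self.to_expr()})"

    def __eq__(self, other):
        if not isinstance(other, ExpPoly):
            return NotImplemented
        return (self - other).is_zero

    def __hash__(self):
        return hash((self.x, sp.srepr(self.to_expr())))


# ---------------------------------------------------------------------------
# constant-coefficient linear ODE solving within the ring
# ---------------------------------------------------------------------------


def linear_operator_coeffs(op_expr: sp.Expr, func: sp.Function, x: sp.Symbol) -> list[sp.Rational]:
    """Extract constant coefficients ``[a0, a1, ...]`` from ``L(u) = sum a_k u^(k)``.

    Verifies that the expression really is a constant-coefficient linear form
    in ``func`` and its derivatives (the homotopy construction requires a
    linear operator).
    """
    e = sp.expand(op_expr)
    max_order = 0
    for d in e.atoms(sp.Derivative):
        if d.expr == func:
            max_order = max(max_order, sum(int(c) for _, c in d.variable_count))
    coeffs = []
    rest = e
    for k in range(max_order + 1):
        tgt = func if k == 0 else sp.Derivative(func, (x, k))
        c = sp.expand(rest).coeff(tgt)
        if c.free_symbols - {x}:
            raise ClosedFormError(f"non-constant coefficient {c} in linear operator")
        if c.has(x):
            raise ClosedFormError(f"non-constant coefficient {c} in linear operator")
        coeffs.append(_as_rational(c) if c != 0 else S.Zero)
        rest = sp.expand(rest - c * tgt)
    if sp.expand(rest) != 0:
        raise ClosedFormError(f"operator is not linear homogeneous in {func}: leftover {rest}")
    while len(coeffs) > 1 and coeffs[-1] == 0:
        coeffs.pop()
    return coeffs


def _char_roots(coeffs: Sequence[sp.Rational]) -> dict[Rational, int]:
    """Roots (with multiplicity) of ``sum a_k z^k``; must all be rational."""
    z = sp.Symbol("_z")
    charpoly = sum(a * z**k for k, a in enumerate(coeffs))
    roots = sp.roots(sp.Poly(charpoly, z))
    if sum(roots.values()) != len(coeffs) - 1:
        raise ClosedFormError("characteristic polynomial does not factor over the rationals")
    out = {}
    for r, m in roots.items():
        if not r.is_Rational:
            raise ClosedFormError(f"irrational/complex characteristic root {r}")
        out[_as_rational(r)] = int(m)
    return out


def _particular_component(coeffs, mu, poly, x, params) -> ExpPoly:
    """Particular solution of ``sum a_k g^(k) = exp(mu x) * poly(x)``."""
    n = len(coeffs) - 1
    # conjugated operator M = sum_j b_j D^j with L(e^{mu x} Q) = e^{mu x} M(Q)
    b = [S.Zero] * (n + 1)
    for k, a in enumerate(coeffs):
        if a == 0:
            continue
        for j in range(k + 1):
            b[j] += a * sp.binomial(k, j) * mu ** (k - j)
    s = 0
    while s <= n and b[s] == 0:
        s += 1
    if s > n:
        raise ClosedFormError("degenerate operator")
    # solve (sum_j b_{j+s} D^j) R = poly by top-down elimination, then Q = I^s R
    bs = [b[j] for j in range(s, n + 1)]
    r = dict(poly)
    R: dict[int, sp.Expr] = {}
    while r:
        d = max(r)
        c = sp.expand(r.pop(d) / bs[0])
        if c == 0:
            continue
        R[d] = R.get(d, S.Zero) + c
        # subtract M_s(c x^d) minus its leading term
        for j in range(1, len(bs)):
            if j > d or bs[j] == 0:
                continue
            fall = S.One
            for i in range(j):
                fall *= d - i
            term = -bs[j] * fall * c
            r[d - j] = sp.expand(r.get(d - j, S.Zero) + term)
            if r[d - j] == 0:
                del r[d - j]
    Q = ExpPoly({S.Zero: R}, x, params)
    for _ in range(s):
        Q = Q.integrate()
    if mu != 0:
        Q = Q * ExpPoly.monomial(S.One, 0, mu, x, params)
    return Q


def solve_linear_ode(
    coeffs: Sequence,
    rhs: ExpPoly,
    conditions: Iterable[tuple[int, sp.Expr, sp.Expr]],
) -> ExpPoly:
    """Solve ``sum_k a_k g^(k)(x) = rhs(x)`` exactly within the ring.

    Parameters
    ----------
    coeffs
        Rational operator coefficients ``[a0, a1, ...]`` (highest order last,
        order one or two in practice).
    rhs
        Right-hand side as an :class:`ExpPoly`.
    conditions
        Point conditions ``(derivative_order, abscissa, value)``; exactly as
        many as the operator order.  Values may involve the declared
        parameters (homogeneous conditions simply use value 0).

    Returns
    -------
    ExpPoly
        The unique exact solution; substituting it back into the operator
        reproduces ``rhs`` identically.
    """
    coeffs = [sp.sympify(a) for a in coeffs]
    order = len(coeffs) - 1
    conditions = list(conditions)
    if len(conditions) != order:
        raise ClosedFormError(
            f"operator order {order} needs {order} conditions, got {len(conditions)}"
        )
    x, params = rhs.x, rhs.params
    particular = ExpPoly.zero(x, params)
    for mu, poly in rhs.terms.items():
        particular = particular + _particular_component(coeffs, mu, poly, x, params)

    # homogeneous basis from rational characteristic roots
    basis: list[ExpPoly] = []
    for root, mult in _char_roots(coeffs).items():
        for j in range(mult):
            basis.append(ExpPoly.monomial(S.One, j, root, x, params))

    consts = [sp.Dummy(f"C{i}") for i in range(len(basis))]
    eqs = []
    for d, a, val in conditions:
        expr = particular.diff(d).eval(a) - sp.sympify(val)
        for ci, bi in zip(consts, basis):
            expr += ci * bi.diff(d).eval(a)
        eqs.append(expr)
    if consts:
        sol = sp.solve(eqs, consts, dict=True)
        if not sol:
            raise ClosedFormError("boundary/initial conditions are not solvable")
        sol = sol[0]
        for ci, bi in zip(consts, basis):
            particular = particular + bi.scale(sp.expand(sol.get(ci, S.Zero)))
    return particular
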