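"""Numerical references, mean-square error, and convergence-control tuning.

The semi-analytic approximants are validated against purely numerical
solutions of the same problems: an adaptive embedded Runge-Kutta 4(5) pair
with dense output for initial-value problems, and a central finite-difference
scheme with Richardson extrapolation over nested grids for two-point
boundary-value problems.

The figure of merit is the mean-square error

    E_m = (1/K) * sum_{j=0}^{K} sum_i [ u_i(j*dt) - u_i,ref(j*dt) ]^2,

i.e. K+1 uniform samples with a 1/K prefactor (kept in exactly this form;
the argmin over the control parameter is invariant to the normalization).
:func:`tune_hbar` sweeps the convergence-control parameter over a uniform
grid — by default substituting into a single hbar-symbolic cascade solution,
which is exactly equivalent to re-running the cascade per grid point — and
returns the grid argmin, ties broken toward the smaller value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline
from scipy.linalg import solve_banded

from .cascade import GHMResult, RationalApproximant, run_ghm
from .homotopy import HomotopyConfig, RationalAnsatz
from .problems import ODESystemProblem, exact

__all__ = [
    "ReferenceSolution",
    "ErrorReport",
    "SweepResult",
    "reference_ivp",
    "reference_bvp",
    "mean_square_error",
    "tune_hbar",
    "absolute_error_curve",
    "hbar_grid",
]


@dataclass
class ReferenceSolution:
    """Dense numerical reference trajectories for a problem's unknowns."""

    grid: np.ndarray
    values: Mapping[str, np.ndarray]
    method: str
    tolerance: float
    interval: tuple
    _dense: Mapping[str, Callable] = field(repr=False, default_factory=dict)

    def __call__(self, unknown: str, t) -> np.ndarray:
        return np.asarray(self._dense[unknown](np.asarray(t, dtype=float)))

    @property
    def unknowns(self) -> tuple:
        return tuple(self.values)


def _first_order_rhs(problem: ODESystemProblem):
    """Solve the residuals for the first derivatives and lambdify."""
    x = problem.var
    funcs = [problem.func(name) for name in problem.unknowns]
    derivs = [sp.Derivative(f, x) for f in funcs]
    sol = sp.solve(problem.residuals_numeric(), derivs, dict=True)
    if not sol:
        raise ValueError("could not solve the residuals for the first derivatives")
    exprs = [sp.expand(sol[0][d]) for d in derivs]
    free = set().union(*(e.free_symbols for e in exprs)) - {x} - set(
        sp.Symbol(u) for u in problem.unknowns
    )
    bad = free - {f.func for f in funcs} - set(funcs)
    bad = {s for s in bad if not isinstance(s, sp.Function)} - set()
    undeclared = [s for s in bad if isinstance(s, sp.Symbol)]
    if undeclared:
        raise ValueError(
            f"cannot integrate numerically with symbolic parameters: {undeclared}"
        )
    syms = [sp.Dummy(name) for name in problem.unknowns]
    exprs = [e.subs(dict(zip(funcs, syms))) for e in exprs]
    fns = [sp.lambdify((x, *syms), e, "numpy") for e in exprs]

    def rhs(t, y):
        return [f(t, *y) for f in fns]

    return rhs


def reference_ivp(
    problem: ODESystemProblem,
    abs_tol: float = 1e-12,
    interval: tuple | None = None,
    n_samples: int = 1001,
) -> ReferenceSolution:
    """Adaptive embedded Runge-Kutta 4(5) reference with dense output.

    The local error is controlled to ``abs_tol`` (both absolute and relative
    tolerances are set to it); evaluation at arbitrary abscissae goes through
    the integrator's dense interpolant.
    """
    if any(c.derivative_order > 0 for c in problem.conditions):
        raise ValueError("reference_ivp supports value conditions only")
    abscissae = {c.abscissa for c in problem.conditions}
    if len(abscissae) != 1:
        raise ValueError("reference_ivp needs all conditions at a single abscissa")
    (t0,) = abscissae
    lo, hi = interval if interval is not None else problem.domain_interval
    lo, hi, t0 = float(lo), float(hi), float(t0)
    y0 = [float(c.value) for name in problem.unknowns for c in problem.conditions_for(name)]
    rhs = _first_order_rhs(problem)
    sol = solve_ivp(
        rhs,
        (t0, hi),
        y0,
        method="RK45",
        dense_output=True,
        rtol=max(abs_tol, 1e-13),
        atol=abs_tol,
    )
    if not sol.success:
        raise RuntimeError(
            f"reference integration failed at t = {sol.t[-1]:.6g}: {sol.message}"
        )
    grid = np.linspace(lo, hi, n_samples)
    dense = {
        name: (lambda t, i=i: sol.sol(t)[i]) for i, name in enumerate(problem.unknowns)
    }
    values = {name: dense[name](grid) for name in problem.unknowns}
    return ReferenceSolution(
        grid=grid,
        values=values,
        method="RK45 (adaptive embedded 4(5), dense output)",
        tolerance=abs_tol,
        interval=(lo, hi),
        _dense=dense,
    )


def _second_order_rhs(problem: ODESystemProblem):
    (name,) = problem.unknowns
    x = problem.var
    f = problem.func(name)
    d2 = sp.Derivative(f, (x, 2))
    sol = sp.solve(problem.residuals_numeric()[0], d2)
    if not sol:
        raise ValueError("could not solve the residual for the second derivative")
    expr = sol[0]
    if expr.has(sp.Derivative):
        raise ValueError("reference_bvp supports y'' = F(t, y) (no y' terms)")
    u = sp.Dummy(name)
    G = sp.lambdify((x, u), expr.subs(f, u), "numpy")
    dG = sp.lambdify((x, u), sp.diff(expr.subs(f, u), u), "numpy")
    return G, dG


def _fd_bvp(G, dG, a, b, ya, yb, n, y_init=None, newton_tol=1e-13, max_iter=50):
    t = np.linspace(a, b, n + 1)
    h = (b - a) / n
    y = np.linspace(ya, yb, n + 1) if y_init is None else y_init.copy()
    y[0], y[-1] = ya, yb
    for it in range(max_iter):
        ti, yi = t[1:-1], y[1:-1]
        res = (y[:-2] - 2 * yi + y[2:]) / h**2 - G(ti, yi)
        diag = -2 / h**2 - dG(ti, yi)
        ab = np.zeros((3, n - 1))
        ab[0, 1:] = 1 / h**2
        ab[1, :] = diag
        ab[2, :-1] = 1 / h**2
        delta = solve_banded((1, 1), ab, -res)
        y[1:-1] += delta
        if np.max(np.abs(delta)) < newton_tol:
            break
    else:
        raise RuntimeError(f"Newton iteration did not converge on the n={n} grid")
    return t, y


def reference_bvp(
    problem: ODESystemProblem,
    abs_tol: float = 1e-10,
    n_start: int = 16,
    max_levels: int = 10,
) -> ReferenceSolution:
    """Central finite differences + Richardson extrapolation over nested grids.

    Second-order central differences give O(h^2) accuracy; combining nested
    grids as ``(4*u_{h/2} - u_h)/3`` cancels the leading error term.  Grids
    are refined until the extrapolated values change by less than
    ``abs_tol``.
    """
    (name,) = problem.unknowns
    conds = sorted(problem.conditions_for(name), key=lambda c: c.abscissa)
    if len(conds) != 2 or any(c.derivative_order != 0 for c in conds):
        raise ValueError("reference_bvp needs two-point value conditions")
    a, b = float(conds[0].abscissa), float(conds[1].abscissa)
    ya, yb = float(conds[0].value), float(conds[1].value)
    G, dG = _second_order_rhs(problem)

    n = n_start
    t_c, y_c = _fd_bvp(G, dG, a, b, ya, yb, n)
    prev_ext = None
    for _ in range(max_levels):
        n *= 2
        y_init = np.interp(np.linspace(a, b, n + 1), t_c, y_c)
        t_f, y_f = _fd_bvp(G, dG, a, b, ya, yb, n, y_init=y_init)
        ext = (4 * y_f[::2] - y_c) / 3  # values on the coarse grid
        if prev_ext is not None:
            # the previous extrapolation grid is every other node of this one
            change = np.max(np.abs(ext[::2] - prev_ext))
            if change < abs_tol:
                break
        prev_ext = ext
        t_c, y_c = t_f, y_f
    else:
        raise RuntimeError(
            f"Richardson extrapolation did not reach {abs_tol} in {max_levels} levels"
        )
    spline = CubicSpline(t_c, ext)
    grid = t_c
    return ReferenceSolution(
        grid=grid,
        values={name: ext},
        method="finite differences (trapezoid/central) + Richardson extrapolation",
        tolerance=abs_tol,
        interval=(a, b),
        _dense={name: spline},
    )


# ---------------------------------------------------------------------------
# error functionals
# ---------------------------------------------------------------------------


@dataclass
class ErrorReport:
    """Mean-square error of an approximant set against a reference."""

    value: float
    K: int
    dt: float
    interval: tuple
    hbar: float | None
    grid: np.ndarray
    abs_errors: Mapping[str, np.ndarray]

    def to_dict(self) -> dict:
        return {
            "E_m": self.value,
            "K": self.K,
            "dt": self.dt,
            "interval": [float(v) for v in self.interval],
            "hbar": None if self.hbar is None else float(self.hbar),
            "max_abs_error": {k: float(np.max(v)) for k, v in self.abs_errors.items()},
        }


def _as_approx_dict(approximants) -> dict[str, RationalApproximant]:
    if isinstance(approximants, RationalApproximant):
        return {approximants.unknown: approximants}
    return dict(approximants)


def _eval_quotient(a: RationalApproximant, t: np.ndarray, param_values=None):
    subs = {sp.Symbol(k) if isinstance(k, str) else k: sp.sympify(v) for k, v in (param_values or {}).items()}
    num = a.numerator.subs(subs) if subs else a.numerator
    den = a.denominator.subs(subs) if subs else a.denominator
    leftover = (num.free_symbols | den.free_symbols) - {a.var}
    if leftover:
        raise ValueError(f"approximant still has free parameters: {sorted(map(str, leftover))}")
    fn = sp.lambdify(a.var, num, "numpy")
    fd = sp.lambdify(a.var, den, "numpy")
    dvals = np.broadcast_to(np.asarray(fd(t), dtype=float), t.shape)
    zero = np.nonzero(dvals == 0.0)[0]
    if zero.size:
        raise ZeroDivisionError(
            f"denominator of {a.unknown} vanishes at the sample point t = {float(t[zero[0]])}"
        )
    nvals = np.broadcast_to(np.asarray(fn(t), dtype=float), t.shape)
    return nvals / dvals


def mean_square_error(
    approximants,
    reference: ReferenceSolution,
    K: int = 500,
    dt: float = 0.1,
    param_values: Mapping | None = None,
    hbar=None,
) -> ErrorReport:
    """``E_m`` over the ``K+1`` samples ``t_j = j*dt`` with the 1/K prefactor."""
    approx = _as_approx_dict(approximants)
    t = np.arange(K + 1) * float(dt)
    lo, hi = reference.interval
    if t[-1] > hi + 1e-12 or t[0] < lo - 1e-12:
        raise ValueError(
            f"reference interval {reference.interval} does not cover [0, {t[-1]}]"
        )
    abs_errors = {}
    total = 0.0
    for name, a in approx.items():
        diff = _eval_quotient(a, t, param_values) - reference(name, t)
        abs_errors[name] = np.abs(diff)
        total += float(np.sum(diff**2))
    return ErrorReport(
        value=total / K,
        K=K,
        dt=float(dt),
        interval=(0.0, float(K * dt)),
        hbar=hbar,
        grid=t,
        abs_errors=abs_errors,
    )


def absolute_error_curve(
    approximants,
    reference: ReferenceSolution,
    n_points: int = 500,
    interval: tuple | None = None,
    param_values: Mapping | None = None,
):
    """Uniformly sampled absolute differences per unknown, plus their maxima.

    Returns ``(grid, errors, max_errors)`` with ``errors[name]`` an array of
    ``|approx - reference|`` values.
    """
    approx = _as_approx_dict(approximants)
    lo, hi = interval if interval is not None else reference.interval
    t = np.linspace(float(lo), float(hi), n_points)
    errors = {
        name: np.abs(_eval_quotient(a, t, param_values) - reference(name, t))
        for name, a in approx.items()
    }
    max_errors = {name: float(np.max(v)) for name, v in errors.items()}
    return t, errors, max_errors


# ---------------------------------------------------------------------------
# convergence-control parameter sweep
# ---------------------------------------------------------------------------


def hbar_grid(lo="0.005", hi="1", step="0.005") -> list:
    """Uniform grid built in exact arithmetic (inclusive endpoints)."""
    lo, hi, step = exact(lo), exact(hi), exact(step)
    if step <= 0 or hi < lo:
        raise ValueError("need lo <= hi and step > 0")
    vals, v = [], lo
    while v <= hi:
        vals.append(v)
        v += step
    if not vals:
        raise ValueError("empty control-parameter grid")
    return vals


@dataclass
class SweepResult:
    """Outcome of a control-parameter sweep: the argmin and the full curve."""

    hbar_star: sp.Expr
    grid: np.ndarray
    errors: np.ndarray
    result: GHMResult | None = None

    def curve(self):
        return np.column_stack([self.grid, self.errors])


def tune_hbar(
    problem: ODESystemProblem,
    config: HomotopyConfig,
    ansatz: RationalAnsatz,
    grid: Sequence,
    K: int = 500,
    dt: float = 0.1,
    abs_tol: float = 1e-12,
    reference: ReferenceSolution | None = None,
    result: GHMResult | None = None,
    method: str = "symbolic",
) -> SweepResult:
    """Mean-square-error sweep of the convergence-control parameter.

    ``method='symbolic'`` (default) solves the cascade once with the control
    parameter symbolic and substitutes each grid value into the assembled
    approximant; ``method='rerun'`` re-runs the whole numeric cascade per
    grid point.  Both routes evaluate the identical exact closed forms and
    agree to rounding.  The argmin of the sampled curve is returned, ties
    broken toward the smaller parameter value.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty control-parameter grid")
    hvals = np.array([float(v) for v in grid], dtype=float)
    order = np.argsort(hvals, kind="stable")
    grid = [grid[i] for i in order]
    hvals = hvals[order]
    if reference is None:
        hi_needed = max(float(K * dt), float(problem.domain_interval[1]))
        reference = reference_ivp(problem, abs_tol=abs_tol, interval=(0, hi_needed))
    t = np.arange(K + 1) * float(dt)
    ref_vals = {name: reference(name, t) for name in problem.unknowns}

    errors = np.empty_like(hvals)
    if method == "symbolic":
        hsym = config.control_parameter
        if not hsym.is_Symbol:
            raise ValueError("symbolic sweep needs a symbolic control parameter")
        if result is None:
            result = run_ghm(problem, config, ansatz)
        fns = {}
        for name, a in result.approximants.items():
            fns[name] = (
                sp.lambdify((a.var, hsym), a.numerator, "numpy"),
                sp.lambdify((a.var, hsym), a.denominator, "numpy"),
            )
        tt = t[:, None]
        hh = hvals[None, :]
        total = np.zeros((len(hvals),))
        for name, (fn, fd) in fns.items():
            vals = np.asarray(fn(tt, hh), dtype=float) / np.asarray(
                fd(tt, hh), dtype=float
            )
            total += np.sum((vals - ref_vals[name][:, None]) ** 2, axis=0)
        errors = total / K
    elif method == "rerun":
        from dataclasses import replace as _replace

        result = None
        for i, hval in enumerate(grid):
            cfg = HomotopyConfig(
                linear_operators=config.linear_operators,
                initial_approximations=config.initial_approximations,
                control_parameter=exact(hval),
                embedding=config.embedding,
            )
            res = run_ghm(problem, cfg, ansatz)
            report = mean_square_error(
                res.approximants, reference, K=K, dt=dt, hbar=float(hval)
            )
            errors[i] = report.value
    else:
        raise ValueError("method must be 'symbolic' or 'rerun'")

    best = int(np.argmin(errors))  # first occurrence = smallest hbar on ties
    return SweepResult(
        hbar_star=grid[best], grid=hvals, errors=errors, result=result
    )
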