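"""Numerical references, the mean-square-error functional, and the sweep."""

import numpy as np
import pytest
import sympy as sp

from ghm import RationalApproximant, run_ghm
from ghm.case_studies import get_case_study
from ghm.problems import ODESystemProblem, PointCondition
from ghm.validation import (
    ReferenceSolution,
    absolute_error_curve,
    hbar_grid,
    mean_square_error,
    reference_bvp,
    reference_ivp,
    tune_hbar,
)


def _decay_problem():
    t = sp.Symbol("t")
    f = sp.Function("theta")(t)
    return ODESystemProblem(
        ("theta",), "t", (sp.Derivative(f, t) + f,),
        (PointCondition("theta", 0, 0, 1),),
        domain_interval=(0, 1),
    )


class TestReferenceIVP:
    def test_exponential_decay_to_closed_form(self):
        ref = reference_ivp(_decay_problem(), abs_tol=1e-12)
        assert abs(float(ref("theta", 1.0)) - np.exp(-1)) < 1e-10

    def test_smoking_conservation_at_tight_tolerance(self, smoking_reference):
        t = np.linspace(0, 50, 501)
        total = sum(smoking_reference(u, t) for u in "nsce")
        assert np.max(np.abs(total - 1)) < 1e-9

    def test_cross_check_against_independent_integrator(self):
        """Dormand-Prince 8th order at halved tolerance agrees to 1e-9."""
        from scipy.integrate import solve_ivp

        cs = get_case_study("heat_radiation")
        problem, _ = cs.build(eps1="0.1", eps2="0.1")
        ref = reference_ivp(problem, abs_tol=1e-12, interval=(0, 5))

        def rhs(t, y):
            th = y[0]
            return [-(th + 0.1 * th**4) / (1 + 0.1 * th)]

        other = solve_ivp(rhs, (0, 5), [1.0], method="DOP853",
                          rtol=5e-13, atol=5e-13, dense_output=True)
        t = np.linspace(0, 5, 101)
        assert np.max(np.abs(ref("theta", t) - other.sol(t)[0])) < 1e-9

    def test_reports_configured_tolerance(self, smoking_reference):
        assert smoking_reference.tolerance <= 1e-12
        assert smoking_reference.interval[1] >= 50


class TestReferenceBVP:
    def test_quadratic_solution_is_exact(self):
        t = sp.Symbol("t")
        f = sp.Function("y")(t)
        p = ODESystemProblem(
            ("y",), "t", (sp.Derivative(f, (t, 2)) + 2,),
            (PointCondition("y", 0, 0, 0), PointCondition("y", 0, 1, 0)),
        )
        ref = reference_bvp(p, abs_tol=1e-10)
        tg = np.linspace(0, 1, 41)
        assert np.max(np.abs(ref("y", tg) - tg * (1 - tg))) < 1e-12

    def test_full_exponential_bratu_richardson_self_consistency(self):
        """Nested-grid agreement at the midpoint, plus an independent oracle."""
        from scipy.integrate import solve_bvp

        p = get_case_study("gelfand").make_problem(kappa=1, taylor_terms=None)
        tight = reference_bvp(p, abs_tol=1e-10)
        loose = reference_bvp(p, abs_tol=1e-7)
        assert abs(float(tight("y", 0.5)) - float(loose("y", 0.5))) < 1e-7

        f = lambda t, y: np.vstack([y[1], -np.exp(y[0])])
        bc = lambda ya, yb: np.array([ya[0], yb[0]])
        tg = np.linspace(0, 1, 101)
        sol = solve_bvp(f, bc, tg, np.vstack([tg * (1 - tg) / 2, 0.5 - tg]), tol=1e-10)
        assert abs(sol.sol(0.5)[0] - float(tight("y", 0.5))) < 1e-9

    def test_zero_forcing_gives_zero_solution(self):
        p = get_case_study("gelfand").make_problem(kappa=0, taylor_terms=None)
        ref = reference_bvp(p, abs_tol=1e-10)
        assert np.max(np.abs(ref("y", np.linspace(0, 1, 11)))) < 1e-12


def _constant_reference(names, value, hi=51.0):
    grid = np.linspace(0, hi, 11)
    dense = {n: (lambda t, v=value: np.full_like(np.asarray(t, float), v)) for n in names}
    return ReferenceSolution(
        grid=grid,
        values={n: dense[n](grid) for n in names},
        method="synthetic constant",
        tolerance=0.0,
        interval=(0.0, hi),
        _dense=dense,
    )


class TestMeanSquareError:
    def test_identical_trajectories_give_zero(self):
        t = sp.Symbol("t")
        a = RationalApproximant("u", sp.Integer(3), sp.Integer(1), t)
        ref = _constant_reference(["u"], 3.0)
        assert mean_square_error(a, ref, K=500, dt=0.1).value == 0.0

    def test_printed_sum_convention_hand_value(self):
        """Constant offset 0.1 on one unknown, K=500: E_m = 501*0.01/500."""
        t = sp.Symbol("t")
        a = RationalApproximant("u", sp.Float(3.1), sp.Integer(1), t)
        ref = _constant_reference(["u"], 3.0)
        report = mean_square_error(a, ref, K=500, dt=0.1)
        assert report.value == pytest.approx(0.01002, rel=1e-12)

    def test_invariant_under_unknown_ordering(self):
        t = sp.Symbol("t")
        a = RationalApproximant("u", sp.Float(1.5), sp.Integer(1), t)
        b = RationalApproximant("w", sp.Float(2.5), sp.Integer(1), t)
        ref = _constant_reference(["u", "w"], 2.0)
        e1 = mean_square_error({"u": a, "w": b}, ref, K=100, dt=0.1).value
        e2 = mean_square_error({"w": b, "u": a}, ref, K=100, dt=0.1).value
        assert e1 == e2

    def test_vanishing_denominator_names_the_point(self):
        t = sp.Symbol("t")
        a = RationalApproximant("u", sp.Integer(1), 1 - t, t)  # pole at t=1
        ref = _constant_reference(["u"], 1.0)
        with pytest.raises(ZeroDivisionError, match="t = 1.0"):
            mean_square_error(a, ref, K=20, dt=0.1)


class TestAbsoluteErrorCurve:
    def test_identical_inputs_give_zeros(self):
        t = sp.Symbol("t")
        a = RationalApproximant("u", sp.Integer(2), sp.Integer(1), t)
        ref = _constant_reference(["u"], 2.0)
        _, errors, mx = absolute_error_curve(a, ref, n_points=50)
        assert np.all(errors["u"] == 0) and mx["u"] == 0.0

    def test_gelfand_error_bound_against_full_exponential_reference(self, gelfand_run):
        """Order-2 quotient vs the untruncated problem: max A.E. below 1e-2."""
        p_full = get_case_study("gelfand").make_problem(kappa=1, taylor_terms=None)
        ref = reference_bvp(p_full, abs_tol=1e-10)
        _, _, mx = absolute_error_curve(gelfand_run.approximants, ref, n_points=201)
        assert mx["y"] < 1e-2

    def test_truncation_order_improves_heat_accuracy(self):
        """Max A.E. does not increase from order 1 to 2 to 3 at eps = 0.1."""
        from ghm.homotopy import make_ansatz

        cs = get_case_study("heat_radiation")
        problem, config = cs.build(eps1="0.1", eps2="0.1")
        ref = reference_ivp(problem, abs_tol=1e-12)
        maxima = []
        for ansatz in (make_ansatz({0, 1}), make_ansatz({0, 1}, {2}),
                       make_ansatz({0, 1}, {2, 3})):
            res = run_ghm(problem, config, ansatz)
            _, _, mx = absolute_error_curve(res.approximants, ref, n_points=101)
            maxima.append(mx["theta"])
        assert maxima[0] >= maxima[1] >= maxima[2]


class TestHbarGrid:
    def test_exact_inclusive_grid(self):
        g = hbar_grid("0.005", "1", "0.005")
        assert len(g) == 200
        assert g[0] == sp.Rational(1, 200) and g[-1] == 1
        assert sp.Rational(53, 200) in g

    def test_empty_or_invalid_grid_is_rejected(self):
        with pytest.raises(ValueError):
            hbar_grid("1", "0", "0.1")
        with pytest.raises(ValueError):
            tune_hbar(None, None, None, [])


@pytest.fixture(scope="module")
def order2(smoking_case):
    """A cheap order-2 smoking cascade for exercising sweep mechanics."""
    from ghm import run_ghm
    from ghm.homotopy import RationalAnsatz

    cs, problem, config = smoking_case
    ansatz = RationalAnsatz.even_odd(1)
    return problem, config, ansatz, run_ghm(problem, config, ansatz)


class TestTuneHbarSmallOrder:
    """Sweep mechanics on a cheap order-2 smoking cascade."""

    def test_argmin_equals_brute_force_minimum(self, order2, smoking_reference):
        problem, config, ansatz, result = order2
        grid = hbar_grid("0.1", "0.5", "0.05")
        sweep = tune_hbar(problem, config, ansatz, grid,
                          reference=smoking_reference, result=result)
        assert float(sweep.hbar_star) == pytest.approx(
            float(grid[int(np.argmin(sweep.errors))])
        )
        assert sweep.errors.min() == sweep.errors[list(map(float, grid)).index(float(sweep.hbar_star))]

    def test_single_point_grid_returns_that_point(self, order2, smoking_reference):
        problem, config, ansatz, result = order2
        sweep = tune_hbar(problem, config, ansatz, [sp.Rational(1, 4)],
                          reference=smoking_reference, result=result)
        assert sweep.hbar_star == sp.Rational(1, 4)

    def test_symbolic_and_rerun_routes_agree(self, order2, smoking_reference):
        problem, config, ansatz, result = order2
        grid = [sp.Rational(1, 5), sp.Rational(2, 5)]
        sym = tune_hbar(problem, config, ansatz, grid,
                        reference=smoking_reference, result=result)
        rerun = tune_hbar(problem, config, ansatz, grid,
                          reference=smoking_reference, method="rerun")
        assert np.allclose(sym.errors, rerun.errors, rtol=1e-10, atol=1e-14)
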