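"""Rational ansatz, Taylor composites, homotopy embedding, cascade derivation."""

import pytest
import sympy as sp
from hypothesis import given
from hypothesis import strategies as st

from ghm.case_studies import HBAR, get_case_study
from ghm.homotopy import (
    P,
    HomotopyConfig,
    RationalAnsatz,
    build_homotopy,
    derive_cascade,
    make_ansatz,
    taylor_form,
)


class TestRationalAnsatz:
    def test_overlapping_powers_are_rejected(self):
        with pytest.raises(ValueError, match="repeated"):
            make_ansatz({0, 1, 2}, {2, 3})

    def test_numerator_must_contain_zero(self):
        with pytest.raises(ValueError, match="p\\^0"):
            make_ansatz({1, 2}, {3})

    def test_denominator_powers_must_be_positive(self):
        with pytest.raises(ValueError):
            make_ansatz({0, 1}, {0, 2})

    def test_even_odd_split(self):
        a = RationalAnsatz.even_odd(6)
        assert a.numerator_powers == frozenset(range(0, 13, 2))
        assert a.denominator_powers == frozenset(range(1, 12, 2))
        assert a.n_functions == 13
        assert a.truncation_order == 12

    def test_contiguous_and_series_degenerate(self):
        a = RationalAnsatz.contiguous(1, 3)
        assert (a.numerator_powers, a.denominator_powers) == (
            frozenset({0, 1}), frozenset({2, 3}))
        s = make_ansatz({0, 1, 2})
        assert s.is_series and s.truncation_order == 2


class TestTaylorForm:
    def test_contiguous_composites_match_hand_expansion(self):
        """(v0 + v1 p)/(1 + v2 p^2 + v3 p^3): known composite coefficients."""
        tf = taylor_form(make_ansatz({0, 1}, {2, 3}))
        v0, v1, v2, v3 = tf.component_symbols
        assert tf.composites[0] == v0
        assert tf.composites[1] == v1
        assert sp.expand(tf.composites[2] + v0 * v2) == 0
        assert sp.expand(tf.composites[3] - (-v0 * v3 - v1 * v2)) == 0

    def test_even_odd_composites(self):
        tf = taylor_form(RationalAnsatz.even_odd(6))
        v = tf.component_symbols
        assert sp.expand(tf.composites[1] + v[0] * v[1]) == 0
        assert sp.expand(tf.composites[2] - (v[2] + v[0] * v[1] ** 2)) == 0

    def test_series_ansatz_is_identity(self):
        tf = taylor_form(make_ansatz(set(range(5))))
        assert all(g == s for g, s in zip(tf.composites, tf.component_symbols))

    def test_gapped_power_sets_are_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            taylor_form(make_ansatz({0, 1}, {3}))

    @pytest.mark.parametrize(
        "ansatz",
        [
            make_ansatz({0, 1}, {2}),
            make_ansatz({0, 1}, {2, 3}),
            RationalAnsatz.even_odd(3),
            make_ansatz({0, 2, 3}, {1}),
        ],
    )
    def test_roundtrip_reexpansion_is_exact(self, ansatz):
        """Composites are exactly the p-power coefficients of num/den."""
        tf = taylor_form(ansatz)
        syms = tf.component_symbols
        num = sum(syms[w] * P**w for w in ansatz.numerator_powers)
        den = 1 + sum(syms[m] * P**m for m in ansatz.denominator_powers)
        series = sum(g * P**k for k, g in enumerate(tf.composites))
        diff = sp.expand(num - den * series)
        T = tf.truncation_order
        for k in range(T + 1):
            assert sp.expand(diff.coeff(P, k)) == 0


class TestBuildHomotopy:
    def test_heat_embedding_matches_reference_form(self):
        """(1-p)(v'+v) + p(v'+v+eps1 v v'+eps2 v^4), which collapses the linear part."""
        cs = get_case_study("heat_radiation")
        problem, config = cs.build()
        h = build_homotopy(problem, config)["theta"]
        tau, v = problem.var, problem.func("theta")
        e1, e2 = sp.symbols("epsilon_1 epsilon_2")
        Lv = sp.Derivative(v, tau) + v
        expected = (1 - P) * Lv + P * (Lv + e1 * v * sp.Derivative(v, tau) + e2 * v**4)
        assert sp.expand(h - expected) == 0
        # simplified form: L(v) + p * (nonlinear bracket)
        simplified = Lv + P * (e1 * v * sp.Derivative(v, tau) + e2 * v**4)
        assert sp.expand(h - simplified) == 0

    def test_reduces_to_linear_deformation_at_p0_and_residual_at_p1(self):
        cs = get_case_study("gelfand")
        problem, config = cs.build()
        h = build_homotopy(problem, config)["y"]
        t, v = problem.var, problem.func("y")
        u0 = config.initial_approximations["y"]
        at0 = h.subs(P, 0).doit()
        assert sp.expand(at0 - (sp.Derivative(v, (t, 2)) - sp.diff(u0, t, 2))) == 0
        assert sp.expand(h.subs(P, 1) - problem.residuals[0]) == 0

    def test_exact_initial_approximation_gives_trivial_cascade(self):
        """With N=0 and u0 the exact solution, all corrections vanish."""
        from ghm import run_ghm
        from ghm.problems import ODESystemProblem, PointCondition

        t = sp.Symbol("t")
        f = sp.Function("u")(t)
        problem = ODESystemProblem(
            ("u",), "t", (sp.Derivative(f, t) + 2 * f,),
            (PointCondition("u", 0, 0, 1),),
        )
        config = HomotopyConfig(
            linear_operators={"u": sp.Derivative(f, t) + 2 * f},
            initial_approximations={"u": sp.exp(-2 * t)},
        )
        res = run_ghm(problem, config, make_ansatz({0, 1}, {2}))
        assert sp.simplify(res.solution.composites["u"][0].to_expr() - sp.exp(-2 * t)) == 0
        for k in (1, 2):
            assert res.solution.composites["u"][k].is_zero

    def test_smoking_hbar_weighted_form(self):
        cs = get_case_study("smoking_spain")
        problem, config = cs.build()
        h = build_homotopy(problem, config)
        t = problem.var
        for name, residual in zip(problem.unknowns, problem.residuals):
            v = problem.func(name)
            expected = (1 - P) * sp.Derivative(v, t) + HBAR * P * residual
            assert sp.expand(h[name] - expected) == 0

    def test_initial_approximation_violating_conditions_is_rejected(self):
        cs = get_case_study("gelfand")
        problem, _ = cs.build()
        t = problem.var
        bad = HomotopyConfig(
            linear_operators={"y": sp.Derivative(problem.func("y"), (t, 2))},
            initial_approximations={"y": t},  # y(1) = 1 != 0
        )
        with pytest.raises(ValueError, match="violates"):
            build_homotopy(problem, bad)

    def test_nonlinear_operator_is_rejected(self):
        cs = get_case_study("gelfand")
        problem, _ = cs.build()
        t = problem.var
        f = problem.func("y")
        bad = HomotopyConfig(
            linear_operators={"y": sp.Derivative(f, (t, 2)) + f**2},
            initial_approximations={"y": t * (1 - t) / 2},
        )
        with pytest.raises(ValueError, match="not linear"):
            bad.validate(problem)


class TestDeriveCascade:
    def test_gelfand_cascade_orders_zero_and_one(self, gelfand_run):
        """Order 0: v0'' + kappa = 0; order 1: v1'' + kappa(v0 + v0^2/2 + v0^3/6)."""
        res = gelfand_run
        problem = res.problem
        t = problem.var
        g0, g1 = (sp.Function(f"y{k}")(t) for k in (0, 1))
        eq0 = next(e for e in res.cascade if e.order == 0)
        kappa = sp.Symbol("kappa")
        assert sp.expand(eq0.expr - (sp.Derivative(g0, (t, 2)) + kappa)) == 0
        assert eq0.conditions == ((0, 0, 0), (0, 1, 0))
        eq1 = next(e for e in res.cascade if e.order == 1)
        expected = sp.Derivative(g1, (t, 2)) + kappa * (g0 + g0**2 / 2 + g0**3 / 6)
        assert sp.expand(eq1.expr - expected) == 0
        assert eq1.conditions == ((0, 0, 0), (0, 1, 0))

    def test_heat_cascade_order_one(self, heat_run_symbolic):
        res = heat_run_symbolic
        tau = res.problem.var
        g0, g1 = (sp.Function(f"theta{k}")(tau) for k in (0, 1))
        e1, e2 = sp.symbols("epsilon_1 epsilon_2")
        eq1 = next(e for e in res.cascade if e.order == 1)
        expected = (
            sp.Derivative(g1, tau) + g1 + e1 * g0 * sp.Derivative(g0, tau) + e2 * g0**4
        )
        assert sp.expand(eq1.expr - expected) == 0
        assert eq1.conditions == ((0, 0, 0),)

    def test_every_cascade_equation_is_linear_in_its_composite(
        self, gelfand_run, heat_run_symbolic
    ):
        for res in (gelfand_run, heat_run_symbolic):
            x = res.problem.var
            for eq in res.cascade:
                assert eq.is_linear_in_unknown(x)

    def test_order_zero_is_linear_deformation(self, heat_run_symbolic):
        """p^0 equation is always L(g0) - L(u0) = 0, i.e. g0 = u0 here."""
        res = heat_run_symbolic
        tau = res.problem.var
        assert sp.simplify(
            res.solution.composites["theta"][0].to_expr() - sp.exp(-tau)
        ) == 0
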