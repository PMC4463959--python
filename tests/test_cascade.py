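"""Cascade solving, component recovery, assembly, and round-trip checks."""

import pytest
import sympy as sp

from ghm import ClosedFormError, make_ansatz, run_ghm, series_residual_check
from ghm.case_studies import get_case_study
from ghm.exppoly import ExpPoly
from ghm.io import approximant_from_json, approximant_to_json


class TestGelfandClosedForms:
    def test_order_zero_is_parabola(self, gelfand_run):
        t = gelfand_run.problem.var
        v0 = gelfand_run.solution.composites["y"][0].to_expr()
        assert sp.expand(v0 + t * (t - 1) / 2) == 0

    def test_order_one_reference_coefficients(self, gelfand_run):
        """All seven published coefficients of v1, exact fractions."""
        t = gelfand_run.problem.var
        v1 = gelfand_run.components["y"][1].to_expr()
        expected = (
            sp.Rational(1, 2688) * t**8 - sp.Rational(1, 672) * t**7
            - sp.Rational(1, 480) * t**6 + sp.Rational(11, 960) * t**5
            + sp.Rational(1, 32) * t**4 - sp.Rational(1, 12) * t**3
            + sp.Rational(589, 13440) * t
        )
        assert sp.expand(v1 - expected) == 0

    def test_order_two_component_is_nonzero_at_origin(self, gelfand_run):
        """Homogeneous conditions sit on the composite g2 = -v0*v2, not on v2."""
        t = gelfand_run.problem.var
        v2 = gelfand_run.components["y"][2].to_expr()
        assert v2.subs(t, 0) != 0
        g2 = gelfand_run.solution.composites["y"][2]
        assert g2.eval(0) == 0 and g2.eval(1) == 0

    def test_auxiliary_polynomial_coefficients_cancel_at_one(self, gelfand_run):
        """delta = v2*3228825600*(t-1) has coefficient sum zero (removable zero)."""
        t = gelfand_run.problem.var
        delta = sp.expand(gelfand_run.components["y"][2].to_expr() * 3228825600 * (t - 1))
        assert delta.subs(t, 1) == 0

    def test_assembled_quotient_meets_boundary_conditions(self, gelfand_run):
        t = gelfand_run.problem.var
        u = gelfand_run.approximant().expr
        assert sp.simplify(u.subs(t, 0)) == 0
        assert sp.simplify(u.subs(t, 1)) == 0


class TestHeatClosedForms:
    def test_order_one_parametric_solution(self, heat_run_symbolic):
        tau = heat_run_symbolic.problem.var
        e1, e2 = sp.symbols("epsilon_1 epsilon_2")
        v1 = heat_run_symbolic.components["theta"][1].to_expr()
        expected = (
            -e1 * sp.exp(-tau) + sp.Rational(1, 3) * e2 * sp.exp(-3 * tau)
            + e1 - e2 / 3
        ) * sp.exp(-tau)
        assert sp.expand(v1 - sp.expand(expected)) == 0

    def test_recovery_divides_by_exponential(self, heat_run_symbolic):
        """v2 = -g2 * e^{tau}: recovery inverts the -v0*v2 composite exactly."""
        res = heat_run_symbolic
        tau = res.problem.var
        g2 = res.solution.composites["theta"][2].to_expr()
        v2 = res.components["theta"][2].to_expr()
        assert sp.expand(v2 + sp.expand(g2 * sp.exp(tau))) == 0

    def test_assembled_quotient_at_origin(self, heat_run_symbolic):
        tau = heat_run_symbolic.problem.var
        u = heat_run_symbolic.approximant().expr
        assert sp.simplify(u.subs(tau, 0) - 1) == 0


class TestRoundTrip:
    def test_series_residual_check_reports_none_when_consistent(
        self, gelfand_run, heat_run_symbolic
    ):
        assert gelfand_run.roundtrip_mismatch() == {"y": None}
        assert heat_run_symbolic.roundtrip_mismatch() == {"theta": None}

    def test_injected_fault_is_caught_at_its_order(self, heat_run_symbolic):
        res = heat_run_symbolic
        name = "theta"
        x = res.problem.var
        components = dict(res.components[name])
        components[1] = components[1] + ExpPoly.constant(1, x, components[1].params)
        order = series_residual_check(
            res.taylors[name], components, res.solution.composites[name]
        )
        assert order == 1


class TestDegenerateCases:
    def test_series_only_ansatz_reproduces_plain_hpm(self):
        """Denominator-free ansatz: approximant equals the HPM partial sum."""
        cs = get_case_study("heat_radiation")
        problem, config = cs.build()
        res = run_ghm(problem, config, make_ansatz({0, 1, 2}))
        partial_sum = sum(
            res.solution.composites["theta"][k].to_expr() for k in range(3)
        )
        assert sp.expand(res.approximant().expr - partial_sum) == 0
        # components coincide with composites for the identity Taylor form
        for k in range(3):
            assert (res.components["theta"][k] - res.solution.composites["theta"][k]).is_zero

    def test_zero_nonlinearity_collapses_to_exact_solution(self):
        cs = get_case_study("heat_radiation")
        problem, config = cs.build(eps1=0, eps2=0)
        res = run_ghm(problem, config, cs.ansatz)
        tau = problem.var
        assert sp.simplify(res.approximant().expr - sp.exp(-tau)) == 0
        for k in range(1, 4):
            assert res.solution.composites["theta"][k].is_zero

    def test_vanishing_order_zero_rejects_rational_ansatz(self):
        """kappa=0 makes v0 = 0, so the denominator component is unrecoverable."""
        cs = get_case_study("gelfand")
        problem, config = cs.build(kappa=0, taylor_terms=4)
        with pytest.raises(ClosedFormError, match="ansatz unusable"):
            run_ghm(problem, config, cs.ansatz)


class TestApproximantObject:
    def test_normalization_fixes_denominator_constant(self, gelfand_run):
        a = gelfand_run.approximant().normalized()
        assert a.denominator.coeff(a.var, 0) == 1
        # normalization does not change the quotient
        b = gelfand_run.approximant()
        assert sp.simplify(a.expr - b.expr) == 0

    def test_json_roundtrip_is_exact(self, gelfand_run):
        a = gelfand_run.approximant()
        doc = approximant_to_json(a)
        back = approximant_from_json(doc)
        assert sp.expand(back.numerator - a.numerator) == 0
        assert sp.expand(back.denominator - a.denominator) == 0

    def test_json_roundtrip_with_exponentials(self, heat_run_symbolic):
        a = heat_run_symbolic.approximant()
        back = approximant_from_json(approximant_to_json(a))
        assert sp.expand(back.numerator - a.numerator) == 0

    def test_numeric_evaluation_matches_substitution(self, gelfand_run):
        a = gelfand_run.approximant()
        f = a.lambdified()
        assert float(f(0.5)) == pytest.approx(float(a(sp.Rational(1, 2))), abs=1e-14)
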