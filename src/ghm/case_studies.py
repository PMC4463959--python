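"""Ready-to-run GHM setups for the three built-in case studies.

Each bundle fixes the choices that make the method concrete for a problem:
the linear operator ``L`` and initial approximation ``u0`` of the homotopy
(``u0`` solves the linear part of the problem under the problem's own point
conditions), the rational ansatz, the embedding form, and the validation
settings (interval, sampling grid for the mean-square error, reference
tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import sympy as sp

from .homotopy import HomotopyConfig, RationalAnsatz, make_ansatz
from .problems import (
    SMOKING_INITIAL,
    ODESystemProblem,
    exact,
    gelfand_problem,
    heat_radiation_problem,
    smoking_model_problem,
)

__all__ = ["CaseStudy", "CASE_STUDIES", "get_case_study", "HBAR"]

#: the convergence-control parameter symbol
HBAR = sp.Symbol("hbar")


@dataclass
class CaseStudy:
    """A problem plus the GHM configuration that reproduces the reference results."""

    name: str
    description: str
    make_problem: Callable[..., ODESystemProblem]
    make_config: Callable[..., HomotopyConfig]
    ansatz: RationalAnsatz
    kind: str  # "ivp" | "bvp"
    em_K: int = 500
    em_dt: float = 0.1
    reference_tol: float = 1e-12
    default_hbar: sp.Expr | None = None

    def build(self, **problem_kwargs):
        problem = self.make_problem(**problem_kwargs)
        return problem, self.make_config(problem)


def _gelfand_config(problem: ODESystemProblem) -> HomotopyConfig:
    t = problem.var
    y = problem.func("y")
    kappa = sp.Symbol("kappa")
    # u0 solves y'' + kappa = 0 with y(0)=y(1)=0 (the linear part of the problem);
    # kappa stays symbolic so the cascade equations keep their parametric form
    return HomotopyConfig(
        linear_operators={"y": sp.Derivative(y, (t, 2))},
        initial_approximations={"y": kappa * t * (1 - t) / 2},
        embedding="classic",
    )


def _heat_config(problem: ODESystemProblem) -> HomotopyConfig:
    tau = problem.var
    th = problem.func("theta")
    # u0 = exp(-tau) solves theta' + theta = 0 with theta(0)=1
    return HomotopyConfig(
        linear_operators={"theta": sp.Derivative(th, tau) + th},
        initial_approximations={"theta": sp.exp(-tau)},
        embedding="classic",
    )


def _smoking_config(problem: ODESystemProblem, hbar=HBAR) -> HomotopyConfig:
    t = problem.var
    # u0_i = the initial proportion of each compartment (constant in time)
    initial = {c.unknown: c.value for c in problem.conditions}
    return HomotopyConfig(
        linear_operators={
            name: sp.Derivative(problem.func(name), t) for name in problem.unknowns
        },
        initial_approximations=initial,
        control_parameter=hbar,
        embedding="hbar",
    )


CASE_STUDIES = {
    "gelfand": CaseStudy(
        name="gelfand",
        description=(
            "Gelfand/Bratu boundary-value problem y'' + kappa*exp(y) = 0 on "
            "[0,1] with cubic polynomial truncation of the exponential; "
            "rational ansatz (v0 + v1*p)/(1 + v2*p^2)"
        ),
        make_problem=gelfand_problem,
        make_config=_gelfand_config,
        ansatz=make_ansatz({0, 1}, {2}),
        kind="bvp",
        em_K=500,
        em_dt=1 / 500,
    ),
    "heat_radiation": CaseStudy(
        name="heat_radiation",
        description=(
            "Lumped convective-radiative cooling theta' + theta + "
            "eps1*theta*theta' + eps2*theta^4 = 0, theta(0)=1; rational "
            "ansatz (v0 + v1*p)/(1 + v2*p^2 + v3*p^3)"
        ),
        make_problem=heat_radiation_problem,
        make_config=_heat_config,
        ansatz=make_ansatz({0, 1}, {2, 3}),
        kind="ivp",
        em_K=500,
        em_dt=0.01,
    ),
    "smoking_spain": CaseStudy(
        name="smoking_spain",
        description=(
            "Four-compartment smoking-habit model for Spain on [0,50] years; "
            "even/odd rational ansatz of order 12 with hbar-weighted "
            "embedding, control parameter tuned by mean-square-error sweep"
        ),
        make_problem=smoking_model_problem,
        make_config=_smoking_config,
        ansatz=RationalAnsatz.even_odd(6),
        kind="ivp",
        em_K=500,
        em_dt=0.1,
        default_hbar=exact("0.265"),
    ),
}


def get_case_study(name: str) -> CaseStudy:
    try:
        return CASE_STUDIES[name]
    except KeyError:
        raise KeyError(
            f"unknown case study {name!r}; available: {sorted(CASE_STUDIES)}"
        ) from None
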