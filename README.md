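# ghm — rational-ansatz generalized homotopy solutions of nonlinear ODEs

`ghm` is a symbolic–numeric solver for nonlinear ordinary differential
equations and small ODE systems, aimed at modellers who want *closed-form
rational approximants* — quotients of short polynomial/exponential
expressions — rather than numerical trajectories or long truncated power
series. Typical users: epidemiologists working with compartmental models,
and physicists/engineers with stiff-ish scalar BVPs/IVPs (thermal ignition,
radiative cooling) who need compact, differentiable, parametric surrogates.

## The method

Write the problem as `L(u) + N(u) − f = 0` with `L` linear and point
conditions. The homotopy embedding

    H(v, p) = (1 − p) [L(v) − L(u₀)] + ℏ p [L(v) + N(v) − f] = 0,   p ∈ [0, 1],

deforms a trivial linear problem (`p = 0`, solved by the initial
approximation `u₀`) into the target equation (`p = 1`); `ℏ` is a
convergence-control parameter (`ℏ = 1` gives the classic embedding). Instead
of the usual power series in `p`, the generalized homotopy method (GHM)
posits a **rational ansatz** whose numerator *and* denominator coefficient
functions are unknowns,

    v = Σ_{w∈W} v_w p^w  /  (1 + Σ_{m∈M} v_m p^m),     W ∩ M = ∅,

e.g. `(v₀ + v₁p)/(1 + v₂p²)` or the even/odd split
`Σ v_{2j} p^{2j} / (1 + Σ v_{2j−1} p^{2j−1})`. Expanding the quotient as a
Taylor series in `p` gives composite coefficients `g_k(v₀,…,v_k)`;
substituting into `H` and equating `p`-powers to zero yields a **cascade of
linear ODEs**, one per composite, each solvable in closed form. The solved
composites are inverted (each order introduces exactly one new component,
linearly), and the `p → 1` limit assembles the rational approximant

    u ≈ Σ_{w∈W} v_w / (1 + Σ_{m∈M} v_m).

The cascade is solved **composite-first** and in **exact rational
arithmetic** over the ring of polynomials × exponentials, so every reported
coefficient is an exact fraction until rounded for display. `ℏ` is selected
by minimizing the mean-square error

    E_m = (1/K) Σ_{j=0}^{K} Σ_i [u_i(jΔt) − u_i,ref(jΔt)]²

against an adaptive Runge–Kutta 4(5) reference (finite differences +
Richardson extrapolation for two-point BVPs).

Three case studies ship built in: the Gelfand/Bratu thermal-ignition BVP
(`gelfand`), lumped convective–radiative cooling (`heat_radiation`), and a
four-compartment model of the evolution of the smoking habit in Spain
(`smoking_spain`).

## Worked example

```python
import sympy as sp
from ghm import run_ghm
from ghm.case_studies import get_case_study
from ghm.validation import absolute_error_curve, reference_bvp

cs = get_case_study("gelfand")                      # y'' + κ e^y = 0, y(0)=y(1)=0
problem, config = cs.build(kappa=1, taylor_terms=4)  # cubic truncation of e^y
result = run_ghm(problem, config, cs.ansatz)         # ansatz (v0 + v1 p)/(1 + v2 p²)

print(result.components["y"][1].to_expr())
u = result.approximant()
print(float(u(sp.Rational(1, 2))))

ref = reference_bvp(cs.make_problem(kappa=1, taylor_terms=None), abs_tol=1e-10)
_, _, mx = absolute_error_curve(result.approximants, ref, n_points=201)
print(mx["y"])
```

prints

```
t**8/2688 - t**7/672 - t**6/480 + 11*t**5/960 + t**4/32 - t**3/12 + 589*t/13440
0.14051933120593035
2.100072156047128e-05
```

The first line is the exact order-1 numerator component (note the exact
fraction 589/13440 as its linear coefficient). The second is the assembled
quotient at the midpoint, and the third the peak absolute error on [0, 1]
against a tight numerical solution of the *untruncated* problem — about
2·10⁻⁵ from an order-2 approximant with eight polynomial coefficients.

More in `examples/`: `gelfand_bvp.py`, `cooling_closed_forms.py`
(fully parametric closed forms in the two radiation coefficients), and
`smoking_control_parameter.py` (the ℏ sweep on the compartmental model).

## Command line

```bash
ghm reproduce gelfand                 # rerun a built-in case study, write artifacts
ghm reproduce smoking --hbar 0.265
ghm run config.yaml                   # declarative problems (see ghm/config.py)
ghm sweep config.yaml                 # E_m curve over an hbar grid + argmin
ghm check gelfand|heat|smoking        # recompute stored reference coefficients
```

Artifacts are plain text: TSV coefficient tables, CSV trajectories and sweep
curves, JSON error reports and serialized approximants, plain-text/LaTeX
expression dumps.

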