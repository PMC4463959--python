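# Methods

## Model and procedure

The solver treats problems of the form `L(u) + N(u) − f = 0` on an interval,
with point conditions at scalar abscissae (initial conditions, or two-point
Dirichlet data). `L` must be linear with constant rational coefficients and
order ≤ 2; `N` may be any polynomial nonlinearity (non-polynomial
nonlinearities such as `exp(y)` are first replaced by a Taylor polynomial of
user-chosen length via `truncate_nonlinearity`). General boundary operators,
PDEs, DAEs, delay and fractional equations are out of scope.

The homotopy is always built as

    H(v, p) = (1 − p)(L(v) − L(u₀)) + ℏ p (L(v) + N(v) − f),

with the control parameter ℏ multiplying only the p-weighted bracket; the
classic embedding is the special case ℏ = 1. No explicit N/f split is ever
needed: the p-weighted bracket is simply the problem's full residual. The
initial approximation u₀ must satisfy every point condition exactly (this is
validated symbolically); for the built-in case studies u₀ solves the linear
part of the problem under the problem's own conditions, which makes the
order-0 cascade equation reproduce the standard textbook form.

### Rational ansatz and cascade

A `RationalAnsatz` is a pair of disjoint p-power sets, numerator W (with
0 ∈ W) and denominator M; the union W ∪ M must cover 0..T contiguously,
where T = |W| + |M| − 1 is the truncation order — this guarantees exactly
one new unknown component per cascade order, i.e. as many equations as
unknowns. The quotient is expanded exactly to order T (`taylor_form`,
implemented by truncated-series inversion of the denominator), giving
composites g_k; substituting the composite series into H and collecting
p-powers yields the cascade (`derive_cascade`).

Two structural decisions, both forced by consistency of the order-2
two-point case:

* **Mechanical expansion only.** Composites and cascade equations are never
  transcribed from any printed source; they are always derived by
  substitution and expansion. (The p² composite of the `{0,1}/{2}` ansatz
  is −v₀v₂; the sign is fixed by the expansion and confirmed by the
  structure of the order-2 equation, which is exactly (−v₀v₂)″ by the
  product rule.)
* **Composite-first conditions.** Homogeneous higher-order point conditions
  are imposed on the composite g_k, not on the individual components. The
  order-k equation is linear in g_k with the unknown entering only through
  L, so each order is a constant-coefficient linear ODE `L(g_k) = rhs`.
  The recovered components may then be nonzero at the condition abscissae
  (the Gelfand order-2 component is), while the assembled quotient still
  satisfies every condition exactly.

### Closed-form solving

All right-hand sides met by the built-in problems live in the ring
{Σ_μ e^{μx} P_μ(x)} with rational exponents and coefficients polynomial in
the declared symbolic parameters (ℏ, the radiation coefficients, κ). The
bespoke solver (`ghm.exppoly`) integrates this ring exactly: particular
solutions per exponential component by conjugating the operator and
eliminating top-down, resonant components (forcing proportional to a
homogeneous solution) by the standard polynomial lift x^m e^{μx}, and the
one or two free constants fixed from the point conditions. Anything outside
the ring raises `ClosedFormError` naming the offending term; there is no
silent numerical fallback. A general ODE black box was deliberately not
used: within the ring the bespoke routine is exact, deterministic, and fast
enough to carry the order-12 system cascade with ℏ symbolic.

Every solved composite is substituted back into its deformation equation at
solve time and the residual must vanish identically; the run aborts
otherwise. `series_residual_check` additionally re-expands the assembled
quotient through the composite relations and verifies order-by-order
agreement.

Component recovery divides by the order-0 component where the ansatz puts
the new unknown in the denominator; the division is exact in the ring
(removable endpoint zeros cancel — for the Gelfand problem g₂ shares the
endpoint zeros of v₀'s factors t and t−1) or fails loudly.

**Arithmetic modes.** The cascade is always computed in exact rational
arithmetic; parameters given as terminating decimals are stored as exact
fractions (0.0425 = 17/400). `mode="floating"` re-renders the stored closed
forms at a configurable precision (default 30 significant digits) and
display output is rounded to 8 significant digits; since the underlying
computation is exact, both modes are bit-stable and the floating mode is a
rendering choice, not a different algorithm.

## Validation layer

* `reference_ivp`: adaptive embedded Runge–Kutta 4(5) (scipy's RK45) with
  dense output, absolute and relative tolerance set to the requested
  tolerance (default 10⁻¹²). "RKF45 with interpolant" is treated as a
  contract — any embedded 4(5) pair with dense output at that tolerance —
  not a mandated implementation; a cross-check against an independent
  8th-order integrator at halved tolerance is part of the test suite.
* `reference_bvp`: second-order central finite differences with Newton
  iteration, nested grid doubling, and Richardson extrapolation
  (4u_{h/2} − u_h)/3 until the extrapolated values change by less than the
  requested tolerance; dense evaluation through a cubic spline on the final
  grid. The Gelfand comparison always uses the *full* exponential problem,
  not the truncated polynomial the cascade solves.
* `mean_square_error` implements E_m exactly as defined for the case
  studies: K+1 samples t_j = jΔt, j = 0..K, prefactor 1/K (not 1/(K+1));
  each compartment is compared against its own reference trajectory. The
  argmin over ℏ is invariant to the normalization, but the printed form is
  kept. Defaults K = 500, Δt = 0.1 (years, for the epidemiological model).
* `tune_hbar` evaluates E_m over a uniform ℏ grid — default (0, 1] with
  step 0.005, which resolves the smoking-model optimum 0.265 at grid
  precision; the grid behind the original study is not documented, so this
  is the package's own choice. The sweep substitutes grid values into a
  single ℏ-symbolic cascade solution; a per-point numeric re-run is
  available (`method="rerun"`) and agrees to rounding, as the test suite
  checks. Ties break toward smaller ℏ.

## Case-study conditions (fixed, not tunable)

* Gelfand: κ = 1, cubic truncation of e^y (4 Taylor terms), ansatz
  `{0,1}/{2}`. The cubic — not quartic — truncation is what the reference
  order-1/order-2 coefficients (589/13440, the auxiliary-polynomial
  constant 31431757) correspond to; `taylor_terms` remains user-settable.
* Cooling: ε₁, ε₂ symbolic by default, ansatz `{0,1}/{2,3}`; numeric demos
  use ε₁ = ε₂ = 0.1. The validation interval [0, 5] is a package choice
  (the original study does not state one).
* Smoking model: rates μ = 0.01, ρ = 0.0425, β = 0.0381, α = 0.1244,
  γ = 0.1175, λ = 0.0498, δ = 0.0498 (per year), initial proportions
  (0.5045, 0.2059, 0.1559, 0.1337) — they sum to exactly 1; even/odd ansatz
  with 2Q = 12; horizon 50 years; E_m with K = 500, Δt = 0.1; reference
  tolerance 10⁻¹².

## Numerical choices and degenerate inputs

* Exponents and operator coefficients must be rational; irrational
  characteristic roots or non-constant coefficients are rejected.
* The denominator-free ansatz degenerates to the classic power-series
  homotopy (plain HPM); composites, components and partial sums coincide,
  which the tests use as an equivalence oracle.
* If the order-0 component vanishes identically (e.g. κ = 0), a
  denominator component's linear coefficient vanishes and recovery rejects
  the ansatz as unusable for that problem — the series ansatz still works.
* Assembled denominators are checked at the condition abscissae; a zero
  there is rejected. During E_m evaluation a vanishing denominator at a
  sample point raises an error naming the point.
* Quotient normalization divides numerator and denominator by the
  denominator's constant coefficient, so coefficient tables are comparable
  across runs (denominator constant term 1).

## Known limitations, and what agreement does/does not show

The published 8-digit decimal tables for the four smoking-model quotients
carry floating round-off of about 10⁻⁷ relative from the original
computation: the unique exact-rational cascade at ℏ = 53/200 matches them
to 7–8 significant digits, and no choice of ℏ improves the fit (the
best-fit ℏ over [0.26, 0.27] is 0.265000 to six digits). The package
therefore compares decimal reference tables at 5·10⁻⁷ relative in
`ghm check` while fractions are compared exactly. All fraction-valued
reference coefficients across the three case studies reproduce identically.

The case studies exercise polynomial and (truncated) exponential
nonlinearities with constant-coefficient linear parts; nothing here shows
how the method fares on problems whose cascade leaves the
polynomial × exponential ring (trigonometric forcing, variable
coefficients), which the solver rejects by design. Accuracy degrades with
distance from the expansion abscissa — the rational structure postpones
but does not remove this — and no systematic rule for choosing the ansatz
order is provided: order selection remains a user decision, guided by the
E_m sweep.
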