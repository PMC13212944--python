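# Methods

## The stability test for incommensurate orders

For a Caputo system `D^{α_i} x_i = f_i(x)` with rational orders
α_i = v_i/u_i, the linearization at an equilibrium is asymptotically stable
iff all roots of `det(diag(λ^{Mα_i}) − J) = 0`, with M a common multiple of
the u_i, satisfy |arg(λ)| > π/(2M). The package reports the signed margin
`π/(2M) − min|arg(λ)|` (negative ⇔ stable). Two conventions for M are
provided:

* **fixed_denominator(d), default d = 100** — α is written as v/d without
  reducing, so every two-decimal order yields M = 100 and the wedge
  threshold π/200 ≈ 0.015708 rad. This is the convention under which the
  published reference values for orders 0.95 and 0.98 were produced, even
  though those fractions reduce (to 19/20 and 49/50). Strictly, the theorem
  behind the test states the coprime form; the discrepancy is harmless
  because of the rescaling property below, but it changes the *numbers*:
  min|arg| and threshold both scale as 1/M, so reproducing printed values
  requires the unreduced convention.
* **reduced** — the coprime pair, giving the smallest M and the cheapest
  polynomial.

**M-rescaling invariance.** Replacing M by kM maps each root λ to its k-th
roots, dividing both min|arg| and the threshold by exactly k and leaving
the verdict unchanged. The test suite asserts this for k ∈ {2, 3}, which is
what makes the two conventions interchangeable for verdicts.

## Root finding

The characteristic determinant is expanded exactly over the polynomial ring
(Leibniz expansion; entries are monomials λ^{Mα_i} minus scalars, and
Mα_i ∈ ℤ by construction), producing a sparse integer-exponent polynomial
of degree M(α₁+1) ≈ 200. Roots come from numpy's balanced companion-matrix
eigenvalues on the dense expansion, then each root is polished by Newton
iteration on the *sparse* form until the correction falls below
1e-13·(1+|λ|). When the computed margin is within 10·tol of the threshold,
the few roots of smallest |arg| are re-polished with 50-digit Newton
(mpmath) before the verdict is issued; an independent oracle test checks
companion roots against mpmath's full multiprecision root isolation at
small M (≤ 12), agreeing to 1e-10 in min|arg|.

**Marginality tolerance.** Verdicts are three-valued with tol = 1e-5 rad:
stable below threshold − tol, unstable above threshold + tol, marginal
between. The published near-critical cases sit 5e-7…3.1e-6 rad from the
threshold and the decisive ones ≥ 3e-5 away, so 1e-5 splits the regimes
with an order of magnitude of slack on both sides. Configurable per call.

**Degenerate inputs.** A zero constant term (root at the origin) raises
`DegenerateRootError` instead of silently dropping λ = 0; it cannot occur
for the chain models' polynomials, whose constant terms are ±aρ ≠ 0.

## Chain models

The two distributed-delay variants share the positive-equilibrium
polynomial `λ^{M(α₁+1)} + aλ^{Mα₁} − ρλ^M + aρ` term-by-term (an exact
determinant identity, asserted over random parameter draws), hence
identical stability maps; their trivial equilibria give constant term −aρ
< 0, which forces a sign change of the polynomial on the positive real
axis, a positive real root, min|arg| = 0 and instability for *every*
parameter choice.

Region scans evaluate the verdict on a rectangular grid (default 60×60
when driven from the CLI; tests use coarser grids) with optional bisection
of the stable/unstable boundary to 1e-4 relative width. Grid axes are open
at 0 (the models assume ρ, a > 0) and an order axis must consist of values
representable under the chosen rationalization convention; the CLI snaps
order axes onto the 1/d lattice, while the library propagates the error.

One caveat on the low-growth plane: the qualitative claim "everything is
stable when ρ ≤ 1" holds on the region with a ≳ ρ. For a < ρ the
α₂-equation feeds back too slowly regardless of ρ (at α₁ → 1 the Jacobian
trace ρ − a is positive), and nodes such as (ρ, a, α₁) = (0.9, 0.8, 0.99)
are genuinely unstable. The region tests therefore sample a ≥ 1 > ρ.

## Discrete-delay critical curves

Crossing frequencies solve
`u^{2α} − 2ρu^α cos(απ/2) + ρ²(1 − 4y*²) = 0`; the radical form uses
**4y*²** (consistent with the squared equation and with the closed-form
boundary), and branch admissibility is decided by the sign of the
right-hand side rather than hard-coded — for y* = 1 the minus branch is
provably negative (√(4 − sin²) > cos) and drops out on its own.

Critical delays are `r = (2nπ ± arccos((u^α cos(απ/2) − ρ)/(−2ρy*)))/u`.
Only the **+arccos family (r₁)** yields genuine roots λ = iu: on the
−arccos family the imaginary part of the characteristic equation carries
the wrong sign (sin(ur) ≤ 0 where it must be ≥ 0 — an artifact of the
squaring step), and since residuals at ±iu are complex conjugates, no root
crosses there at all. r₂ delays are still computed (and always exceed
r₁(0), which the tests assert), but only r₁ points are residual-validated
to 1e-9 against the characteristic equation.

**Transversality.** Re(dλ/dr) at a crossing is computed both from the four
real components z₁…z₄ and from the compact numerator identity
`rρu^{α+1}(1 − sin(απ/2)) + αu^{2α} − ruρ² cos(απ/2)`; the two agree to
1e-9 by exact algebra (asserted at every call) and are positive on all
sampled critical points — positivity is *tested*, not assumed, since no
general proof is available for all parameter ranges.

**Monotonicity of the boundary.** r₁(0) shrinks as ρ grows (verified at
all sampled orders; at α = 1 it is exactly π/(3√3ρ)). In the order
direction the residual-validated formulas give a boundary that *rises*
with α for ρ ≥ 1 (e.g. ρ = 1: r₁(0) = 0.300 at α = 0.5 up to 0.6046 at
α = 1, non-monotone only at small ρ): stronger memory (smaller α) shortens
the stable delay window. Prose summaries sometimes state the opposite
direction for α; the tests encode the direction the formulas produce,
which also matches the chain-model behaviour (stability regions shrink as
α₁ decreases).

## The fractional Adams integrator

The solver is the standard fractional Adams–Bashforth–Moulton PECE method:
product-rectangle predictor weights (k+1)^α − k^α and product-trapezoid
corrector weights on the Volterra form of the initial-value problem, each
component of an incommensurate system advanced with its own order's
weights. One corrector sweep per step, full-history memory term, no
short-memory truncation — reproducibility over speed; a step costs O(n)
and a horizon-T run O((T/h)²). Accuracy checks: the integer-order limit
reproduces e^{−t}; D^{1/2}-relaxation matches a truncated Mittag-Leffler
series to 1e-3; the empirical order on a smooth linear test is ≥ 1
(error at least halves when h halves).

Defaults: h = 2⁻⁷ (tests use 2⁻⁶ to keep the suite fast — the regime
labels are insensitive to this), horizon adaptive from T = 50 doubling to
T_max = 400 until the classifier decides. The delayed-logistic variant
aligns the delay to the grid (r snapped to the nearest multiple of h, with
a warning when inexact) and reads the delayed state by index shift, from
the history function before t = 0.

**Initial states.** The chain variable starts at y(0) = 0 by its integral
definition. The default x0 = 0.5 is a small founder population: it lies in
the basin of every regime at moderate growth rates (ρ ≈ 4.5–6), where runs
reproduce the predicted behaviours — sustained oscillation at marginal
parameters, relaxation onto (a², a) resp. (a, a) at stable ones. Two
caveats, both verified against a classical ODE integrator at α = 1 rather
than being solver artifacts: (i) from x0 near the equilibrium *with
y(0) = 0* the transient overshoots and escapes in finite time — the quiet
start of the memory variable is a genuinely different initial condition
from "near equilibrium"; (ii) at the strongly growing marginal rows
(ρ ≈ 14.65 and 22.91) the bounded orbits' basin does not intersect the
y = 0 slice at all, so exhibiting the oscillation there requires the
explicit y0 override near the equilibrium (and at ρ = 22.91 the orbit is
only weakly protected — nearby starts still escape slowly). Regime
reproduction is therefore exercised on the moderate-growth rows.

**Divergence.** Finite-time blow-up is real in these models (the quadratic
delayed term has no a-priori bound); the integrator flags the step index
and truncates rather than propagating NaNs, and the classifier labels the
run divergent.

**Regime classifier.** A trajectory is *converged* when the tail window
(last 25%) has relative peak-to-peak below 1e-3 in every component,
*periodic* when the tail oscillation has stopped changing (the two tail
half-windows agree in amplitude to 20%) without decaying, *divergent* on
the overflow flag, else *undecided*. Trajectories shorter than 100 steps
are rejected as unclassifiable.

## Synthetic parameter draws

Property tests draw (α₁, ρ, a) with α₁ uniform on the two-decimal lattice
[0.05, 0.99] (so every draw is representable under the default convention)
and ρ, a log-uniform on [0.1, 100] — three decades around the published
parameter rows. These draws exercise the exact structural identities
(model equivalence, trivial-equilibrium instability, M-rescaling); they
are parameter samples, not data, so no claim about measurement noise or
model misspecification is being tested.

## Known limitations

* Only weak (chain length 1) exponential kernels; gamma kernels of higher
  order and general distributed kernels are out of scope.
* Orders must be rational with modest denominators; the wedge criterion
  degenerates (threshold → 0) as M grows, and irrational orders are not
  supported.
* The solver is explicit-predictor based and untruncated: stiff systems or
  very long horizons are expensive; no adaptive step control.
* Verdicts are local (linearization) statements; basins of attraction are
  only probed empirically by the simulator.
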