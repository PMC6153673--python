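# Methods

## Model and conventions

The state is a pair of non-negative integer counts (X, Y) evolving by the
eight reactions listed in the README.  Intra-type competition propensities
use the distinct-pair count, X(X−1)/(aM) and Y(Y−1)/(dM); the mean-field
limit X²/(aM) of the deterministic equations differs by O(X/M), which
vanishes in the scaling limit and is below Monte Carlo resolution at
M = 100 (it shifts the monomorphic stationary mean by about one
individual).  The cross-type reactions at rates XY/(bM) and XY/(cM) remove
one X and one Y respectively.

Scaled variables: x = X/M, y = Y/M, mutant fraction p = x/(x+y), scaled
total size z = x + y.  The weak-selection theory assumes both types share
the birth rate β and death rate γ with β > γ; the simulator and the
deterministic integrator accept unequal rates, but every weak-selection
entry point validates equality and refuses otherwise, since the first-order
theory is silent about that case.

Throughout, the *study conditions* are β = 0.6, γ = 0.1, M = 100 unless a
caller overrides them; with a = 1 this puts the monomorphic population at
a(β−γ)M = 50 individuals, small enough that demographic noise matters.

## Exact simulation

The jump process is simulated by the direct stochastic simulation
algorithm: exponential waiting time at the total propensity, categorical
reaction choice, two uniforms per event.  The inner loop is numba-compiled
(~2·10⁷ events/s), which is what makes 20,000-replicate Monte Carlo
estimates per parameter cell affordable on one CPU.  Each replicate owns a
private RNG stream seeded from one word of a `SeedSequence` spawned from
the user-facing master seed; the word sequence is prefix-stable, so growing
`n_runs` extends a batch without re-randomizing earlier replicates, and
identical (spec, X0, Y0, seed) reproduce trajectories bit-for-bit.

Timeouts (event budget `max_events = 10⁷` or an explicit `t_max`) are a
third outcome class: they are excluded from fixation estimates with a
warning and never silently counted as losses, keeping the estimator
unbiased conditional on absorption.  Fixation estimates carry Wilson
confidence intervals (statsmodels).

## The ψ boundary-value problem

The first-order amplitude ψ(z) solves a linear second-order ODE with two
printed regimes that differ in their d-scalings (interior-equilibrium
games vs. dominance games); both are implemented exactly as stated, with no
harmonized form.  z = 0 is a singular point.  Frobenius analysis gives the
bounded behaviour at the origin,

* internal regime: ψ(z) → z/(3(β+γ)d), indicial exponents {3, −2};
* dominance regime: ψ(z) → z/((β+γ)d), indicial exponents {2, −1},

and the far-field balance z((β−γ)d − z)ψ′ + z ≈ 0 gives the outflow slope
ψ′(z_max) = 1/(z_max − (β−γ)d).  These two conditions close the problem:
the Dirichlet value at z_min = 10⁻³ and the Neumann slope at
z_max = 10·d(β−γ) (default; well above the carrying-capacity scale).
z_max-insensitivity is verified in the tests: doubling z_max moves ψ on the
lower half of the window by < 10⁻⁴ relative.

In the dominance regime the particular solution resonates with the
indicial exponent 2, producing a z² ln z term whose unbounded higher
derivatives defeat collocation in the raw variable (the solver pours its
entire mesh budget into a micro-interval at z_min).  The solver therefore
works in t = ln z — a mesh uniform in t is geometric in z, dense near the
singular origin, and renders e^{2t}·t perfectly smooth.  `scipy`'s
collocation BVP solver (`solve_bvp`, tolerance 10⁻⁸) then converges for
both regimes in under 0.1 s at M = 100.  The returned solution carries the
ODE residual evaluated on the 2000-point geometric output grid with the
second derivative taken from the collocation spline; typical maxima are
~10⁻⁹, and solutions failing strict positivity or monotonicity are
rejected outright.

Consistent with the published remark about instability at large population
scales, the collocation stops converging for M beyond a few thousand; this
surfaces as a `RuntimeError` with mesh diagnostics rather than a silently
degraded solution.

An independent cross-check lives in the test suite: a one-shot, direct
second-order finite-difference solve of the same linear BVP on a 60,000
point geometric mesh (banded solve, no collocation, no adaptivity) agrees
with the production solver to 10⁻⁴ relative on z ∈ [0.1, 2].  A
shooting-method oracle is impossible here: the homogeneous equation has a
mode growing like exp(2M∫(z−(β−γ)d)/((β+γ)d+z)dz) ≈ e¹⁰⁰ across the
domain, which annihilates double precision.

Between grid points ψ is interpolated with a shape-preserving monotone
cubic (PCHIP), so positivity and monotonicity survive interpolation.  One
ψ solve is cached per (regime, d, β, γ, M) — the amplitude depends on the
payoffs only through d, so a payoff sweep over (a, b, c) reuses it.

## First-order fixation probabilities

`phi_weak_selection` dispatches on the game class: the interior-equilibrium
formula for coexistence/coordination, the dominance formula otherwise, and
φ = p for exactly neutral specs (a = b = c = d).  Boundary equalities in
the payoff comparisons (a = c or b = d without full neutrality) are
assigned to the dominance classes, where the dominance formula remains
valid; the interior-equilibrium theorem does not cover those boundaries.
The formula is exact at p ∈ {0, 1} and satisfies φ(p\*, z) = p\* to machine
precision by construction (the factor 1 − p/p\* vanishes).

The first-order value can leave [0, 1] when selection is immoderate; the
returned result carries both the raw and the clamped value, plus a flag
raised whenever any weak-selection condition magnitude — (1−d/b)²,
(1−d/b)(2−d/c−d/b), (1−d/b)(1+d/a−2d/b), (1−d/b)(1/p\*−2), and the
dominance analogue — exceeds 0.1.  The threshold marks the edge of the
trust region, not a hard validity boundary.

`generator_apply` evaluates the transformed (p, z) generator — five
partial-derivative terms — on a gridded surface with central finite
differences, as a residual oracle: the exact absorption probability
annihilates it, constants annihilate it, and the first-order surface
leaves a residual that scales as (1−d/b)², verified by the ratio test at
b = 1.02 vs 1.04 on a 193×161 grid (measured ratio 3.83 against the ideal
3.85).  Grid sizes are chosen so that finite-difference truncation error
sits well below the physical residual; the surface is cubic in p, for
which the second central difference is exact and the first has O(h²)
error.

## Diffusion level and the center-manifold projection

The two-type SDE system (Itô) is integrated by Euler–Maruyama with
independent Gaussian increments, default dt = 10⁻³; a coordinate proposed
below zero is set to zero and frozen.  This truncation biases absorption
slightly (a diffusion path can touch zero and re-enter between grid
points), which is why the SDE-vs-jump-process consistency test uses a
0.03 absolute band at 5,000 paths rather than a purely statistical one.

`scale_fixation_probability` computes hitting probabilities of a generic
1-D diffusion as S(q0)/S(q_hi), with the inner log-density integral
accumulated separately by adaptive quadrature and exponentiated under a
max-shift so strong drift cannot overflow; the constant-drift-ratio
closed form is reproduced to 10⁻¹⁰.

The center-manifold projected diffusion has drift
q(1−q)(1/d − 1/b − (1/a + 1/d − 1/b − 1/c)q) and variance
2βq(1−q)/(M(β−γ)²) on [0, 1].  Mapping an initial condition (p, z) onto
the manifold is genuinely ambiguous off-manifold.  Since z is the *fast*
variable (the population size equilibrates before frequencies move), the
default projection conserves the mutant frequency:
q0 = pd/(pd + (1−p)a), which reduces to q0 = p for a = d and coincides
with the literal coordinate q0 = pz/(a(β−γ)) on the manifold.  With this
default the projection and the weak-selection formula agree within 0.05
across p ∈ [0.2, 0.8] and z ∈ {0.2, 0.75} at M = 100.  The literal
mapping is available as `mapping="manifold"`; it is exact on the manifold
and degrades badly off it (documented in the tests), which mirrors the
published discussion of projection error for starts far from the manifold.

## Comparison formulas

The Otto–Whitlock, Kimura–Ohta and Uecker–Hermisson formulas are evaluated
exactly as printed, with the translations s = 1/d − 1/b, r = β − γ,
K = (β−γ)aM, birth rate β and neutral replacement rate ξ = 0; the
Kimura–Ohta effective-size factor is Q = KzM(s+r)/(sK + rzM).  They are
meaningful for frequency-independent specs (a = b, c = d) and an
advantageous mutant (s > 0); other inputs warn or raise.  Exponentials use
expm1/log1p throughout — at s ≈ 0.025 and Q ≈ 50 naive exponentials lose
digits — and each formula is pinned in the tests against an extended
precision sympy re-evaluation (50 digits, exact rationals) to 10⁻¹⁰.  The
general-frequency branching formula 1 − (1 − φ₁)^{pzM} uses the real
exponent pzM and reduces to φ₁ exactly at p = 1/(zM).

These formulas assume Ms ≫ 1 and deterministic ecology, conditions the
fluctuating-size model deliberately violates (here Ms ≈ 2.6); the package
makes no claim about their ordering relative to the weak-selection value
and instead verifies that the weak-selection prediction tracks the exact
simulation best in this regime.

## Monte Carlo scale and preset experiments

The preset experiments (`fig1` … `fig10`) pin the published figure
parameter grids.  The original figures averaged 100,000 simulations per
point; the presets default to 10,000 — chosen so a full preset runs in
minutes on one CPU — widening confidence intervals by √10, and accept an
override for full-scale runs.  Presets whose payoff values were carried
only in figure legends (`fig3`, `fig4`, `fig6`) use representative
parameter choices of the stated game class, recorded in the preset
descriptions.  The acceptance script uses 10,000 replicates for the
neutral check and 20,000 per cell for the simulation-vs-theory comparison;
at that size the 3-standard-error band is ~0.01, comfortably inside the
0.02 agreement bound it verifies.

Initial counts for a (p, z) cell are X0 = round(pzM), Y0 = round((1−p)zM);
the comparison is made against φ at the *rounded* frequency X0/(X0+Y0),
since at zM = 75 rounding shifts p by up to 0.007, which is resolvable at
20,000 replicates.

## Known limitations

* The ψ solver is reliable for M up to ~10³; beyond that it raises.
* The first-order formula degrades smoothly as payoff spreads grow; the
  conditions flag at 0.1 is advisory.  Clamping to [0, 1] is honest but
  crude for strongly selected coordination games.
* Euler–Maruyama absorption carries O(√dt) boundary bias; no Milstein or
  exact-boundary scheme is provided.
* The synthetic study conditions (two types, well-mixed, common birth and
  death rates for the analytic layer) are exactly the model's assumptions;
  passing tests certify the implementation against the model, not the
  model against any particular biological population.
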