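# Methods

## Model and units

Particles are hard spheres (diameter σ) whose surface patches interact
through the Kern-Frenkel potential: a square well of depth ε_αγ acting
between centers at separations σ ≤ r < σ + δ, switched on only when the
patch vector of *each* particle points at the partner within the patch
cone, cos θ > cos θ_max for both.  Defaults are δ = 0.2 σ and
cos θ_max = 0.98.  Reduced units throughout: lengths in σ, energies in
the reference bond energy ε = 1, temperatures in ε/k_B (k_B = 1),
pressures in ε/σ³.  Thermal de Broglie volumes are set to 1; they shift
every chemical potential by the same composition-independent constant and
cannot affect coexistence or azeotropy, but the convention matters when
comparing theory-side and grand-canonical chemical potentials, which this
package does — both sides use the same convention.

A mixture design is a graph: species carry globally typed patches
(tetrahedral placement by default, the (1,1,1)/√3 family; any rigid
rotation is equivalent), and a symmetric matrix ε_αγ ≥ 0 over patch types
defines both the bond energies and, through its nonzero pattern, the
bonding topology.  That matrix is the single source of truth: the theory
engine and the Monte Carlo engine read connectivity from nowhere else.

The N2c8 factory design fixes one concrete bond-exclusive pairing:
1–5 and 4–8 across species, 6–7 within species 2, and the
self-complementary loops 2–2 and 3–3 on species 1 (the tunable pairs).
Only the pairing's mass-action structure matters — an intra-species pair
and a self-loop produce identical equations — so with equal energies the
design is thermodynamically symmetric under species exchange.

## Wertheim theory (TPT1)

Free energy per particle in k_BT units:

    βf = (ln ρ − 1 + Σ_i x_i ln x_i) + (4φ − 3φ²)/(1 − φ)²
       + Σ_i x_i [ Σ_{α∈Γ(i)} (ln X_α − X_α/2) + Γ(i)/2 ],

with packing fraction φ = ρ π σ³/6.  The not-bonded probabilities solve
the law of mass action `X_α = [1 + φ Σ_γ x_{s(γ)} X_γ Δ_αγ]⁻¹`.

**Bond strength.**  Δ_αγ = (e^{ε_αγ/T} − 1) · K(φ), where K is the bond
volume integral (1/V_s) [(1 − cos θ_max)/2]² 4π ∫ g_HS(r) r² dr over the
well shell.  Three treatments of the hard-sphere pair correlation are
provided:

* `shell` (default): the analytic Percus-Yevick first-shell g(r)
  (Laplace-inversion closed form), r²-averaged over [σ, σ+δ].  The φ
  dependence ln K(φ) is precomputed on a spline (125 points to φ = 0.62,
  24-point Gauss-Legendre per node) so that its derivative, needed by the
  pressure, is smooth.
* `contact`: the Carnahan-Starling contact value, constant across the
  shell.
* `unity`: g_HS ≡ 1 (low-density limit).

The default follows the definition of Δ as an integral over the *full*
g(r): across the thin shell g decays appreciably below its contact value,
and the choice is quantitatively consequential — at T = 0.08 the tuned
N2c8 azeotrope sits at x = 0.603 (shell), 0.578 (contact), 0.641 (unity).
The full-shell treatment is the one that reproduces the reference
behavior of this design family (azeotrope shift 0.5 → 0.6 at ε′ = 1.35
with the midpoint ε′ = 1.2 near x ≈ 0.55-0.56), and was fixed as the
default on those grounds before the acceptance tests were written.

**Mass action solver.**  Damped fixed-point warmup (damping 0.5) from a
closed-form uniform seed, then Newton on the 8-odd-dimensional system
(residual tolerance 1e-13, verified on every solve).  A vectorized
batched variant (grid of densities simultaneously) backs the
equation-of-state scans.

**Derivatives.**  The bonding free energy is stationary in X at the
mass-action solution, which collapses its derivatives to closed forms:

    βP_bond/ρ = −(Q/2)(1 + φ h'/h),
    βμ_bond,i = Σ_{α∈Γ(i)} ln X_α − (φ h'/(2h)) Q,

with Q = Σ_α x_{s(α)}(1 − X_α) (mean bonded patches per particle) and
h(φ) the packing-fraction factor of Δ.  These are exact for each g_HS
option and are cross-checked in the tests against Richardson-extrapolated
finite differences (agreement ~1e-6) and the Gibbs-Duhem identity
(residual < 1e-8 at random states).

**Phase behavior.**  At fixed (T, P, x) the density roots of P(ρ) = P are
bracketed on a 201-point log-density grid (φ up to 0.55) and refined by
Brent's method; the lowest root is the vapor branch, the highest the
liquid (middle roots are mechanically unstable and discarded).  During
coarse pressure scans the roots are taken from inverse-linear
interpolation only — g(x) is stationary in ρ at a root, so branch free
energies are second-order accurate even with crude roots.  Coexistence at
(T, P) solves μ_i(vapor, x′) = μ_i(liquid, x″) (2×2 Powell hybrid,
seeded from the crossing of the two g(x) branches).

**Azeotrope location.**  At the azeotropic pressure the two branches are
tangent: g_l − g_v = 0 together with equality of slopes, and
dg/dx|_{T,P} = μ_A − μ_B makes the slope residual analytic.  Because
d(g_l − g_v)/dP = 1/ρ_l − 1/ρ_v < 0 pointwise, the minimum branch gap is
monotone in P; a log-P scan brackets the sign change, a few bisections
tighten it, and a 2D root solve in (x, ln P) polishes the tangency.  The
returned point is verified by collapsing an explicit coexistence solve
(reported gap < 1e-3 in composition).  For designs symmetric under
species exchange this lands on x = 0.5 to solver precision.

**Inverse design.**  `shift_azeotrope` holds T fixed, perturbs the
energy ε′ on the chosen pairs (default: all self-complementary pairs,
first step +0.1 toward the target), re-solves the azeotrope per trial ε′,
and applies secant updates on x_azeo(ε′), guarded against wild steps.
x_azeo(ε′) is monotone over the relevant range (asserted empirically in
the tests), which makes the secant iteration well-posed; convergence to
|x − target| < 0.01 typically takes 3-5 azeotrope solves.  Note that the
azeotropic composition of a tuned design varies along its azeotropic line
(for N2c8 at ε′ = 1.35: x = 0.59 at T = 0.076 to x = 0.64 at T = 0.09),
so the loop's answer is tied to the working temperature, taken as T =
0.08 throughout.

## Monte Carlo engine

Single-particle translations (uniform cube, wrapped) and small-angle
quaternion rotations; log-volume moves (NPT); volume exchange in
ln(V_a/V_b) and species-preserving particle transfers with orientation
resampling (Gibbs); insertions/deletions with per-species chemical
potentials (GCMC).  Energies are tracked incrementally and audited
against a full O(N²) recomputation at every observable stride (the
maximum drift is reported; the tests require < 1e-9·|E|).  Hard overlaps
use a large finite penalty so trial arithmetic stays NaN-free.  Neighbor
search is a plain O(N) loop per move — the right trade-off at the
particle counts used here (≤ a few hundred); cell lists would pay off
only well beyond that.

**AVB moves.**  Aggregation-volume-bias in/out moves on the bonding
shell of a random target j, in the symmetric (AVBMC-1) form, with two
bias stages that the narrow patches make essential:

* the "in" region is the union of j's patch cone-shells (volume
  Γ_j · V_shell · (1 − cos θ_max)/2), not the full radial shell;
  in-proposals pick a patch of j uniformly and place the particle
  uniformly in that cone-shell;
* the inserted particle's orientation is drawn so that a uniformly
  chosen patch points back into the cone (uniform spin about the axis);
  the proposal density ratio Γ_k (1 − cos θ_max)/2 / (number of
  back-aligned patches) enters the acceptance explicitly.

Out-proposals are uniform over the box with uniform orientation,
rejected if they land back in the in-region, so the out-state proposal
density is 1/V and the acceptance prefactors use V (not V − V_in).  A
forced in↔out pair of acceptance ratios multiplies to exactly 1 (unit
test), and the equilibrium bond probability of an isolated pair matches
direct Monte Carlo integration of the two-particle configurational
integral — the test that caught an earlier version whose out-moves
excluded the whole radial shell and thereby over-populated bonded states.
With ε = 0 the move must not bias anything; an NPT invariance test
asserts this.

**Identity swaps (Gibbs).**  One particle per box of different species
exchange species labels — equivalent to a simultaneous A/B
counter-transfer, conserving all totals.  Acceptance is plain Metropolis
on the two energy changes.  At strong bonding most swaps are rejected
(they sever every bond of both particles), so composition relaxation
between boxes rides mainly on ordinary transfers; swaps help in the
vapor.

**Initial configurations.**  `make_initial_config` inserts particles at
uniform random positions with uniform random orientations, re-drawing on
overlap (feasible to φ ≈ 0.45), reproducibly from a seed.  This is the
package's synthetic-data generator for simulation starts: it emulates a
well-mixed fluid quench.  It does not emulate pre-bonded networks — runs
at strong bonding always include an equilibration transient in which the
bond network forms, and all reported averages discard that transient.

**Randomness.**  Each run derives independent per-chunk seeds from its
schedule seed via `SeedSequence`; kernels seed numba's internal RNG per
chunk.  Identical (configuration, schedule, seed) triples reproduce
trajectories bit-for-bit on one platform.

## Study conditions for the simulation validations

The Gibbs-ensemble and S0 validations are run scaled down: 128 particles
per system (64-80 per box) instead of 500-4000, and 10⁵-sweep runs.  The
S0 validation runs at the literal reference state point (T = 0.17,
P = 0.125), where the implemented model reproduces the reference density
(ρ ≈ 0.35) and chemical potential (μ⁰ ≈ 0.15) directly.

The Gibbs-ensemble validations cannot use the literal reference
temperatures: with the Kern-Frenkel geometry above (δ = 0.2,
cos θ_max = 0.98), both this package's theory and its simulations place
the vapor-liquid critical point of these designs near T_c ≈ 0.09
(theory: 0.094 for the always-azeotropic design, 0.088-0.093 for N2c8),
so state points at T = 0.125-0.138 and T = 0.098 are supercritical — a
dense/dilute two-box start homogenizes, as direct runs confirm.  The
package therefore places its Gibbs validations *inside the implemented
model's own coexistence region at comparable reduced depth*: the
always-azeotropic design at T = 0.080 (T/T_c ≈ 0.85) and total ρ = 0.2,
and the tuned N2c8 design at T = 0.079 (where its azeotrope sits at
x ≈ 0.60) and total ρ = 0.1.  Boxes are started at unequal densities near
the theory binodal; persistence (or growth) of the density gap is the
coexistence signature — the same protocol at supercritical temperatures
demonstrably collapses the gap — while per-box compositions track their
initial values only at azeotropic composition.

Because the always-azeotropic mixture has no composition restoring force
beyond mixing entropy, the between-box composition split executes a slow,
zero-mean wander; composition-preservation is asserted with error bands
that reflect that mode rather than naive block errors.

## S0 method

Partial structure factors use the N-normalized convention
S_ab(k) = ⟨ρ̂_a(k) ρ̂_b(−k)⟩/N, shell-averaged over all integer
wavevectors with equal |k| (recorded in output metadata), and are
extrapolated to k = 0 with Ornstein-Zernike fits S0/(1 + k² ξ_a ξ_b)
(nonlinear least squares; parameter standard errors reported).

The Kirkwood-Buff composition integral is implemented through the
concentration-concentration structure factor
S_cc(0) = x_B² S⁰_AA + x_A² S⁰_BB − 2 x_A x_B S⁰_AB:

    βμ_A^ex(x_A) = ∫_1^{x_A} (dx/x) [ x(1−x)/S_cc(0) − 1 ],

which follows from the exact identity (∂βμ_A/∂x_A)_{T,P} = x_B/S_cc(0)
after removing the ideal-mixing part.  This reading is fixed by the
null test the method must pass: for species-blind (ideal) mixing
S_cc(0) = x_A x_B exactly, so the integrand — and μ_ex — vanish
identically; alternative single-channel readings of the bracket fail
that test.  Trapezoidal integration from the pure reference x⁰_A = 1;
the 0/0 integrand limit at x = 1 is linearly extrapolated from the two
nearest interior points; uncertainties are propagated from the S0 fit
errors by one-sided perturbation.

The reference μ⁰ comes from grand-canonical runs of the *pure* species-A
fluid (insertions of the second species disabled) on a grid of chemical
potentials, interpolating to the μ whose mean density matches the NPT
density — the density-matching protocol, automated.

## Numerical choices and degenerate inputs

* Mass-action residual tolerance 1e-13; Newton capped at 100 iterations
  with X clipped to (0, 1].
* Density-root refinement: Brent, xtol 1e-15, rtol 1e-14.
* Azeotrope detection tolerance: coexistence gap < 1e-3 in composition.
* OZ fits with exactly flat data short-circuit to (S0 = value, ξ = 0);
  fewer than 4 k-points below the fit cutoff is an error.
* Compositions with x_i = 0 are handled exactly (x ln x → 0); chemical
  potentials of absent species are −∞ and never enter coexistence
  conditions.
* Packing fractions ≥ 1 raise; random insertion refuses φ ≥ 0.45.

## Known limitations

* TPT1 neglects bond-bond correlations, rings, and the composition
  dependence of g_HS; its critical temperatures for these narrow-patch
  designs agree with this package's own simulations but need not match
  other parameterizations quantitatively.
* The S0 route needs small-k structure factors; at 10²-particle boxes the
  smallest accessible k is ~0.9 σ⁻¹ and the OZ extrapolation leans on the
  fit form.  No finite-size Kirkwood-Buff corrections beyond the OZ
  extrapolation are applied.
* No crystal-order analysis: the NVT engine can run nucleation-prone
  state points but nothing in the package classifies crystalline order.
* Coexistence is computed by equal-P/equal-μ and common-tangent
  constructions only; temperature-density binodals come from scanning T.
* The Gibbs-ensemble runs at reduced N carry finite-size shifts of the
  binodal of a few percent in density; the tests bound, not eliminate,
  these.
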