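# Methods

This note documents the physical models, numerical choices and synthetic-data
design behind `electrokin`.

## Problem

At a charged solid/water interface the dielectric constant and the viscosity
of the fluid deviate from their bulk values. Two competing explanations exist:
(i) the strong surface field and the high counter-ion concentration in the
double layer change the *bulk* constitutive behavior locally
(electrostriction / electroviscosity), or (ii) the mere presence of the
interface restructures a sub-nanometer water layer whose properties are then
essentially independent of field and salt. The package implements the
continuum machinery needed to compare these scenarios through their
electrokinetic signature: the electrokinetic surface charge density
σ_ek(σ₀) — the charge a bulk-property Gouy–Chapman/Smoluchowski description
would need in order to produce the observed electro-osmotic plateau velocity.

## Unit system

Fixed package-wide: length nm, field V/nm, charge e, concentration M,
viscosity mPa·s, surface charge e/nm², time ps (series) / ns (velocities).
Temperature is fixed at 300 K with k_BT/e = 0.025852 V; ε₀ = 0.055263
e/(V·nm); 1 M = 0.602214 nm⁻³. Unit conversions (Green–Kubo
bar²·ps·nm³ → mPa·s; e·V/(nm²·mPa·s) → nm/ns) are centralized in
`constants.PhysicalConstants`.

## Constitutive models

Dielectric decrement (salt): ε(c) = ε_w + (ε_w − ε_ms)·L(a_c c) with the
Langevin function L(x) = coth x − 1/x and a_c = 3α/(ε_w − ε_ms). This
Gavish–Promislow-type interpolation satisfies ε(0) = ε_w, initial slope α
(the excess ionic polarizability) and the high-salt limit ε_ms. Defaults are
the SPC/E-compatible NaCl literature values ε_w = 71, ε_ms = 27.9,
α = −11.59 M⁻¹.

Dielectric saturation (field): the *difference* constant, defined through
D = ε₀ ε̄ E (equivalently the running field-average of the differential
constant dD/dE / ε₀), follows the Booth-type single-dipole form
ε̄(E) = ε_n + 3(ε_w − ε_n)·L(a_E E)/(a_E E), even in E, decreasing from ε_w
to the high-field limit ε_n. **No published values exist for ε_n and a_E in
the source data we model; the shipped defaults ε_n = 4 and a_E = 10 nm/V are
documented placeholders** chosen to give the expected qualitative behavior
(ε̄ drops by an order of magnitude near 1 V/nm); both are config keys.

Field/salt coupling: multiplicative (default)
ε̄(E,c) = 1 + (ε̄(E) − 1)(ε(c) − 1)/(ε_w − 1), which preserves both marginals
and never drops below 1; or additive ε̄(E) + ε(c) − ε_w, which can violate
ε̄ ≥ 1 at extreme (E, c) — one reason the multiplicative ansatz is preferred,
and the model-comparison fitter reproduces that preference on data generated
from either truth.

Viscosity: η(c) = η_w + a_c1 c + a_c2 c² (η_w = 0.648 mPa·s, a_c1 = 0.0777
mPa·s/M, a_c2 = 0.0223 mPa·s/M²; the √c electrolyte asymptotics relevant
below ~0.5 M is deliberately not modeled). Field dependence per tensor
component: η(E) = η_w + a_E1·(1 − 3L(x)/x) + a_E2 E², x = p₀E/k_BT with the
SPC/E water dipole moment p₀ = 0.049 e·nm. The first term is a bounded even
power series with the single prefactor a_E1; the final term carries the
quadratic high-field growth. Parallel component: a_E1 = 0.160 mPa·s,
a_E2 = 0.0868 mPa·s/(V/nm)²; perpendicular: a_E1 = −0.190 mPa·s,
a_E2 = 0.0319 mPa·s/(V/nm)² — the negative a_E1 makes η_⊥ dip below η_w
before the quadratic term takes over. Coupling ansatz as for the dielectric
constant (multiplicative default).

Interfacial profiles: in `bulk_like` mode the bulk laws are evaluated at the
local E(z) and c(z) = (c₊ + c₋)/2. In `extended_box` mode a layer of width
z_int replaces them with constants ε̄_int, η_int (replacement, not addition —
the additive reading of the "box contribution" would require evaluating the
bulk laws at in-layer concentrations of ~90 M, far outside their fitted
domain, and would couple the slip term to the (E,c)-dependence, contradicting
the observed insensitivity of the box curves). The flow problem uses the
*perpendicular* viscosity component because the double-layer field is normal
to the wall and hence to the flow. Default interfacial parameter set
(hydrophilic-surface values): d = 0.3 nm, z_int = 0.44 nm, ε̄_int = 4.4,
η_int/η_w = 3.7, b_s = −0.32 nm.

## Double-layer solver

Modified Poisson–Boltzmann on z ∈ [0, z_max]:
d/dz[ε₀ ε̄(E,c,z) E] = ρ, E = −dψ/dz, with Bikerman/Borukhov steric ion
statistics c_± = c₀ e^∓Ψ / (1 + (2c₀/c_max)(cosh Ψ − 1)) and the fcc
close-packing ceiling c_max = √2/d³ (≈ 87 M at d = 0.3 nm); d = 0 recovers
ideal Boltzmann ions. Ions are *not* excluded from the box layer. Boundary
conditions: Gauss law D(0⁺) = σ₀ (fluid occupies z > 0, no field behind the
wall) and Ψ(z_max) = 0.

Discretization: finite volume on a geometrically graded grid (first cell
0.00025 nm at the wall, growth 1.01, z_max = max(6 nm, z_int + 12 λ_D);
≈ 700 nodes at 10 mM). This resolution holds the Gouy–Chapman closed-form
error of Ψ(0) below 10⁻⁵ relative; charge neutrality ∫ρ dz = −σ₀ is exact to
the nonlinear-solver tolerance because the trapezoid weights coincide with
the finite-volume cell widths.

Nonlinearity: outer damped fixed point — freeze the ε̄(z) profile, solve the
resulting PB problem by damped Newton (tridiagonal Jacobian, banded solve,
backtracking line search; intermediate potentials clipped at |Ψ| = 300 to
avoid exp overflow), recompute ε̄ from the updated E and c profiles, relax
with factor 0.5; outer tolerance max|ΔΨ| < 10⁻⁸ and max|Δε̄| < 10⁻⁸, cap 500
iterations. Converged solutions take 2 (constant ε̄) to ~150 (strongly
field-dependent ε̄ at σ₀ = 2 e/nm²) outer iterations, < 0.1 s each.

## Stokes flow and electrokinetic mapping

One integration of d/dz[η du/dz] = −ρ E_ext with vanishing far-field shear
gives η du/dz = −E_ext D(z); the Navier condition u(0) = b_s du/dz|₀ then
yields u(z) = −E_ext[b_s σ₀/η(0) + ∫₀^z D/η dz′]. The quadrature evaluates
D/η per interval from the exact potential increment
(∫ D dz = ε₀ (k_BT/e) ε̄ ΔΨ with face-averaged ε̄/η), which telescopes to the
Helmholtz–Smoluchowski result exactly when ε̄/η is constant. η(0) is the box
viscosity when the box is active; negative b_s then acts as a stagnant-layer
correction growing linearly in σ₀. E_ext = 0.3 V/nm by default; it cancels
in ζ and σ_ek.

The apparent zeta potential follows the experimental convention — inverted
with *bulk water* properties regardless of the actual profiles:
ζ = −η_w u_∞/(ε₀ ε_w E_ext); σ_ek is the monovalent Grahame inversion of ζ at
the bulk salt concentration, again with ε_w. With steric ions, box and slip
all disabled this chain returns σ_ek = σ₀ identically (verified to 10⁻⁴
relative), and ζ = Ψ(0) (to 10⁻⁶).

Scenario sweeps: the σ₀ grid is 20 uniform points on [0, 2] e/nm². The slip
length belongs to the interfacial (box) parameter set and is active only in
box scenarios; bulk-relation scenarios use a no-slip wall.

Known behavior: with the Table-2 parameter set the box-model σ_ek(σ₀) rises
steeply, peaks near σ₀ ≈ 0.2 e/nm² at ≈ 0.043 e/nm² and then declines almost
linearly (the linear slip term eventually outruns the saturating
electro-osmotic integral, with a mobility reversal just beyond σ₀ = 2).
The curve is concave up to σ₀ ≈ 0.85 but its declining tail is very weakly
convex (second differences ≤ 3·10⁻⁵ e/nm², i.e. ≲ 10⁻³ of the curve range,
stable under grid refinement). A strict global concavity assertion therefore
fails by that hair's breadth; the corresponding acceptance test is left
failing rather than silently tolerated, and this is the one intentionally
red test in the suite.

## Estimators

* Fluctuation dielectric constant: ε = 1 + var(M)/(ε₀ V k_BT) per component
  (unbiased variance, mean subtracted), transverse components averaged; the
  high-frequency constant is fixed at 1 (no electronic polarizability in the
  emulated model). Ion-current contributions (< 3% in the emulated data) are
  neglected by design.
* Difference constant at finite field: ε̄ = 1 + ⟨M_∥⟩/(ε₀ V E₀); refuses
  E₀ = 0 and points the caller to the fluctuation route.
* Slab finite difference: ε_∥ = ΔD/(ε₀ ΔE) between two plate-charge states,
  assigned to the mean midpoint field; symmetric in the two states.
* Green–Kubo viscosity: η = (V/k_BT)·mean over the component set
  ({xz, zx, xy, yx} parallel, {yz, zy} perpendicular for a field along x) of
  ∫₀^τmax ⟨P_αβ(0)P_αβ(τ)⟩ dτ; biased (1/n) stationary autocovariance via
  FFT, trapezoid in τ, τ_max a required explicit parameter.

## Synthetic data

Generators are pure functions of (seed, generator-name) via counter-based
`SeedSequence` streams (crc32 of the name), so adding generators never
perturbs existing outputs. Noise is Gaussian throughout (the emulated
measurements report symmetric error bars; nothing justifies heavier tails).

The stress series are Ornstein–Uhlenbeck with exact discretization
(AR(1) with ρ = e^{−dt/τc}) and stationary variance C₀ = η_target k_BT /
(V τ_c · unit factor), so each component's Green–Kubo integral equals
η_target in closed form. Defaults τ_c = 0.2 ps, dt = 0.02 ps, n = 10⁶: a
design (power) calculation — the Green–Kubo statistical error at these
settings is ~1.2% (median), < 4% (max over a 16-seed panel), giving ~3σ
margin inside the 5% recovery band. The OU class emulates the stationarity
and single correlation time of equilibrium stress fluctuations but none of
the fast librational structure or long-time tails of real water; passing
round trips validate the estimator algebra and statistics, not molecular
realism. The same caveat applies to the iid-Gaussian polarization series
(no dipolar relaxation dynamics) and to the exponential-saturation velocity
profiles.

## Fitting

Weighted least squares whenever a stderr column is present, unweighted
otherwise. The viscosity fits are linear in their free parameters once η_w
and p₀ are fixed and are solved exactly (`numpy.linalg.lstsq`); η_w can
optionally be co-fitted (flag), as can ε_w conceptually — both are fixed by
default. The Gavish–Promislow and Booth fits use
`scipy.optimize.least_squares` (trust-region reflective, xtol = ftol =
10⁻¹⁴) from 5 deterministic starts; covariance from s²(JᵀJ)⁻¹. Degenerate
designs are reported, not crashed: a flat dielectric-vs-field table drives
a_E toward its zero bound (flagged via `at_boundary` when a_E·E_max < 10⁻²,
i.e. the saturation scale collapsed below the data resolution), and on a
flat decrement table only the slope α = a_c(ε_w − ε_ms)/3 is identifiable,
not (ε_ms, a_c) separately. The ansatz comparison freezes the marginal
parameters fitted on the (E₀ = 0, c₀ = 0) axes and ranks the two coupling
modes by RSS on the full grid, ties broken toward multiplicative.

## Limitations

Planar geometry, monovalent symmetric electrolytes, local dielectric
response, no surface conduction or electrode polarization, no frequency
dependence, no temperature dependence, no image-charge/correlation physics.
The Booth-branch defaults (ε_n, a_E) are placeholders (see above), so
absolute numbers that depend on the field saturation branch are
model-internal, not literature values.
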