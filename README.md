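# electrokin

Continuum electrokinetics of charged aqueous interfaces with field- and
salt-dependent dielectric constant and viscosity.

## What this is for

At hydrophilic charged surfaces the electro-osmotic mobility saturates with
increasing surface charge, and the interfacial water layer has a dielectric
constant and viscosity far from bulk. Is that caused by the strong
double-layer field and counter-ion crowding acting through *bulk*
constitutive laws, or by the intrinsic restructuring of the first water
layer at the wall? `electrokin` implements the continuum toolchain to ask
that question quantitatively:

* **Constitutive models** — dielectric decrement with salt
  (Gavish–Promislow form, ε_ms = 27.9, α = −11.59 M⁻¹ for NaCl), dielectric
  saturation with field (Booth form for the difference constant ε̄ defined by
  D = ε₀ε̄E), a quadratic viscosity–salt law and an even, bounded-plus-
  quadratic viscosity–field law per tensor component, coupled
  multiplicatively or additively.
* **Modified Poisson–Boltzmann solver** for a charged planar half-space:
  d/dz[ε₀ ε̄(E(z), c(z), z) E(z)] = ρ(z) with Bikerman steric ions
  (fcc ceiling c_max = √2/d³) and an optional interfacial "box" layer
  (width z_int, constants ε̄_int, η_int).
* **Electro-osmotic Stokes flow** with Navier slip:
  u(z) = −E_ext[b_s σ₀/η(0) + ∫₀ᶻ D/η dz′], plateau velocity u_∞, apparent
  zeta potential ζ = −η_w u_∞/(ε₀ ε_w E_ext) and the electrokinetic surface
  charge density σ_ek = 2ε₀ε_w κ (k_BT/e) sinh(ζ/2) — both deliberately
  evaluated with bulk-water ε_w, η_w, as experiments do.
* **Estimators** for (synthetic) trajectory data: static dielectric constant
  from polarization fluctuations (ε = 1 + var(M)/(ε₀Vk_BT)), difference
  constant from the mean polarization at finite field, slab finite-difference
  differential constant, and Green–Kubo shear viscosity from off-diagonal
  stress autocorrelations.
* **Fitting machinery** recovering all constitutive coefficients from
  tabulated measurements, and a model comparison that ranks the
  multiplicative vs additive field/salt coupling ansatz.
* **Synthetic-data generators** with exact ground truth (Gaussian
  polarization, Ornstein–Uhlenbeck stress, saturating velocity profiles,
  noisy measurement tables) standing in for molecular-dynamics output.

## Worked example

Solve the double layer and flow for a hydrophilic wall at σ₀ = 1 e/nm²,
c₀ = 10 mM with the interfacial box layer (d = 0.3 nm, z_int = 0.44 nm,
ε̄_int = 4.4, η_int = 3.7 η_w, b_s = −0.32 nm):

```python
from electrokin import (DielectricModel, ViscosityModel, InterfaceSpec,
                        ProfileMode, solve_double_layer, solve_flow)

spec = InterfaceSpec(sigma0=1.0, c0=0.01, profile_mode=ProfileMode.EXTENDED_BOX)
dl = solve_double_layer(spec, DielectricModel())
fl = solve_flow(dl, spec, ViscosityModel())
print(f"psi0 = {dl.psi0:.2f} kT/e, u_inf = {fl.u_inf:.2f} nm/ns, "
      f"zeta = {fl.zeta_reduced:.2f} kT/e, sigma_ek = {fl.sigma_ek:.4f} e/nm2")
```

prints

```
psi0 = 10.34 kT/e, u_inf = -5.36 nm/ns, zeta = 0.71 kT/e, sigma_ek = 0.0254 e/nm2
```

— a bare charge of 1 e/nm² produces the electrokinetic signature of only
0.025 e/nm²: the surface potential is huge (10 k_BT/e, counter-ions near
their 87 M steric ceiling), but the low-permittivity, high-viscosity,
negative-slip interfacial layer suppresses nearly all of the electro-osmotic
flow that a bulk-property description would predict.

The numbered drivers under `analysis/` run the full study and write tables
under `results/`:

```
python analysis/01_simulate_bulk.py --seed 1   # synthetic measurement campaign
python analysis/02_fit_constitutive.py         # recover all fit coefficients
python analysis/03_estimate_from_trajectories.py
python analysis/04_double_layer_profiles.py    # bulk-like vs box profiles
python analysis/05_electrokinetic_sweep.py     # sigma_ek(sigma0) scenarios
```

`05_electrokinetic_sweep.py` reports, per scenario, σ_ek across
σ₀ ∈ [0, 2] e/nm²: steric repulsion alone pushes σ_ek *above* σ₀
(up to 10% at σ₀ = 2), bulk-like (E, c)-dependence bends it to ~0.5–1 e/nm²,
while every extended-box variant caps it at ≈ 0.04 e/nm² with all box curves
within 0.4% of each other — the interfacial layer dominates and the local
field/salt dependence is negligible on top of it.

A thin CLI wraps the same library (`electrokin synth|fit|estimate|solve|sweep`,
see `--help`); every run writes a manifest with the config hash and seed.

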