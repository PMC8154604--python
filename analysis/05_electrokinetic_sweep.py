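#!/usr/bin/env python
"""Electrokinetic surface charge density vs bare surface charge density.

Sweeps sigma0 for the continuum scenarios at c0 = 10 mM:

* bulk-relation scenarios (no interfacial layer): constant properties,
  and bulk-like (E, c)-dependent dielectric constant and/or viscosity --
  steric ion repulsion makes sigma_ek exceed sigma0, and none of these
  curves saturates the way measured electrokinetic data do;
* extended-box scenarios: the interfacial water layer (eps 4.4,
  eta 3.7 eta_w, slip length -0.32 nm over 0.44 nm) caps sigma_ek at a
  few hundredths of an e/nm^2, and toggling the (E, c)-dependence on
  top of the box moves the curves by well under 5% of their range --
  the interfacial layer, not electrostriction or electroviscosity,
  controls the electrokinetics.

Also verifies the bare-charge identity: with every effect disabled the
pipeline returns sigma_ek = sigma0.
"""

import argparse
from pathlib import Path

import numpy as np

from electrokin import io as ekio
from electrokin.constitutive import DielectricModel, InterfaceSpec, ViscosityModel
from electrokin.flow import SCENARIOS, sweep_sigma0

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results/sweeps"))
parser.add_argument("--n-sigma0", type=int, default=20)
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

sigma0 = np.linspace(0.0, 2.0, args.n_sigma0)
spec = InterfaceSpec(c0=0.01)

curves = {}
for name in SCENARIOS:
    df = sweep_sigma0(name, sigma0, spec)
    df.to_csv(args.out / f"curve_{name}.csv", index=False)
    curves[name] = df.sigma_ek_e_per_nm2.values
    print(f"{name:>10}: sigma_ek at sigma0=1 is {np.interp(1.0, sigma0, curves[name]):.4f}, "
          f"max {curves[name].max():.4f} e/nm^2")

ratio = curves["constant"][1:] / sigma0[1:]
print(f"\nsteric constant-property scenario: sigma_ek/sigma0 in "
      f"[{ratio.min():.3f}, {ratio.max():.3f}] (> 1 everywhere)")

scale = np.abs(curves["box_const"]).max()
worst = max(np.abs(curves[n] - curves["box_const"]).max() / scale
            for n in ("box_eps", "box_eta", "box_both"))
print(f"extended box: toggling (E, c)-dependence moves sigma_ek by at most "
      f"{100 * worst:.1f}% of the curve scale (lines overlap)")

# bare-charge identity with every effect off
ideal = InterfaceSpec(c0=0.01, d=0.0, z_int=0.0, b_s=0.0)
const_eps = DielectricModel(eps_w=71.0, eps_ms=1.0, alpha=0.0, eps_n=71.0)
const_eta = ViscosityModel(a_c1=0, a_c2=0, a_E1_par=0, a_E2_par=0,
                           a_E1_perp=0, a_E2_perp=0)
df = sweep_sigma0("constant", [0.01, 0.1, 0.5, 1.0], ideal,
                  const_eps, const_eta)
df.to_csv(args.out / "curve_identity.csv", index=False)
err = np.abs(df.sigma_ek_e_per_nm2 / df.sigma0_e_per_nm2 - 1).max()
print(f"identity limit: max |sigma_ek/sigma0 - 1| = {err:.2e}")
print(f"curve tables written to {args.out}")
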