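#!/usr/bin/env python
"""Generate the synthetic bulk 'measurement' campaign.

Emulates the bulk simulation outputs the downstream analysis consumes:
noisy and noise-free dielectric/viscosity tables on an (E0, c0) grid, a
polarization time series at the pure-water dielectric constant, an
Ornstein-Uhlenbeck stress series at the pure-water viscosity, and a
noisy channel velocity profile.  Everything is written as delimited
text under results/synthetic/.
"""

import argparse
from pathlib import Path

from electrokin import io as ekio
from electrokin.synth import (
    SyntheticConfig,
    gen_dielectric_table,
    gen_polarization_series,
    gen_stress_series,
    gen_velocity_profile,
    gen_viscosity_table,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/synthetic"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

GRID = dict(E0_grid=tuple(i * 0.25 for i in range(9)),
            c0_grid=tuple(i * 0.25 for i in range(9)))

clean = SyntheticConfig(seed=args.seed, **GRID)
noisy = SyntheticConfig(seed=args.seed, noise_eps=0.5, noise_eta=0.005, **GRID)

for tag, cfg in (("clean", clean), ("noisy", noisy)):
    ekio.write_measurement_table(gen_dielectric_table(cfg),
                                 args.out / f"dielectric_{tag}.csv")
    ekio.write_measurement_table(gen_viscosity_table(cfg),
                                 args.out / f"viscosity_{tag}.csv")

pol = gen_polarization_series(71.0, volume=125.0, n=100_000, dt=0.02,
                              seed=args.seed)
ekio.write_trajectory(pol, args.out / "polarization_series.csv")

stress = gen_stress_series(0.648, tau_c=0.2, volume=125.0, n=200_000,
                           dt=0.02, seed=args.seed)
ekio.write_trajectory(stress, args.out / "stress_series.csv")

gen_velocity_profile(-20.0, 0.3, 6.0, noise=0.2, seed=args.seed).to_csv(
    args.out / "velocity_profile.csv", index=False)

ekio.write_manifest(args.out, seed=args.seed)
print(f"synthetic campaign written to {args.out} "
      f"(seed {args.seed}; 4 tables, 2 series, 1 profile)")
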