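"""Kinetic descriptors: Einstein diffusion fit and roto-vibrational RMSF.

Generates Brownian particles with a prescribed diffusion coefficient
(1.0 x 1e-10 cm^2/s, the scale of drug mobility in a glassy polymer) across
four replicate seeds, fits the centre-of-mass MSD, and reports the replicate
mean +/- standard deviation. Then recovers the equipartition fluctuation
sqrt(3 kT / k) from atoms in harmonic wells.
"""

import math

from asdmix import diffusion_coefficient, msd, replicate_stats, rmsf
from asdmix.constants import D_NM2_PS_TO_1E10_CM2_S
from asdmix.synthetic import gen_brownian, gen_harmonic

d_in = 1e-8  # nm^2/ps = 1.0 x 1e-10 cm^2/s
per_seed = []
for seed in range(4):
    top, traj = gen_brownian(n_mol=100, d=d_in, dt=2.0, n_frames=10_000, seed=seed)
    res = diffusion_coefficient(msd(traj, top, "particle"))
    per_seed.append(res.d)
    print(f"replicate {seed}: D = {res.d:.3f} x 1e-10 cm^2/s  (fit r^2 = {res.fit_r2:.4f})")
mean, std = replicate_stats(per_seed)
target = d_in * D_NM2_PS_TO_1E10_CM2_S
print(f"replicate mean: D = {mean:.3f} +/- {std:.3f} x 1e-10 cm^2/s (input {target:.1f})")

k, kt = 1000.0, 2.494  # kJ/mol/nm^2 and kT at ~300 K
top_h, traj_h = gen_harmonic(n_atoms_per_mol=5, n_mol=20, k=k, kt=kt,
                             n_frames=10_000, seed=1)
res_h = rmsf(traj_h, top_h, "blob")
print(f"\nharmonic-well RMSF: {res_h.heavy_atom_mean:.5f} nm "
      f"(equipartition sqrt(3kT/k) = {math.sqrt(3 * kt / k):.5f} nm)")
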