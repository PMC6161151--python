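"""Descriptor ranking against experimental amorphicity indices.

Loads the bundled descriptor table (eight drug-polymer blends at 40 wt %
drug load), computes per-drug descriptor ranges, the Spearman association
of each descriptor with the amorphicity index, and classifies whether
thermodynamics (mixing energy) or kinetics (mobility) limits each drug's
stability ranking.
"""

import warnings

from asdmix import (
    classify_limiting_factor,
    descriptor_range,
    descriptor_stability_association,
    energy_trend,
    mixing_energy,
)
from asdmix.datasets import load_stability_descriptors

table = load_stability_descriptors()
print(table.to_string(index=False))

for api in ("FLA", "PAC"):
    de = descriptor_range(table, api, "delta_ecoul")
    dd = descriptor_range(table, api, "d")
    print(f"\n{api}: mixing-energy range {de:7.1f} kJ/mol, "
          f"diffusion range {dd:.2f} x 1e-10 cm^2/s")
    for desc in ("delta_ecoul", "d"):
        a = descriptor_stability_association(table, api, desc)
        print(f"  {desc:12s} vs AI40: Spearman {a.spearman:+.3f}  Pearson {a.pearson:+.3f}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # the table carries no replicate spreads
        verdict = classify_limiting_factor(table, api)
    print(f"  rate-limiting factor: {verdict}")

fla = table[table["api"] == "FLA"]
blends = {
    row.polymer: mixing_energy(row.delta_ecoul, 0.0, 0.0, n_api=190, n_pol=10,
                               volume=190.0)
    for row in fla.itertuples()
}
print(f"\nFLA polymer ranking by mixing energy (best first): {energy_trend(blends)}")
print("negative with PVP/EEC (favourable mixing), positive with PSA/PAA")
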