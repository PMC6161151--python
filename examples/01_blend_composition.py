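"""Blend bookkeeping: compose drug-polymer blends at target drug loads.

Builds the 2 APIs x 4 polymers x 2 concentrations blend matrix from
molecular masses, then cross-checks the bundled literature composition
table: recomputed API weight percents should match the printed ones to 0.1
percentage points on the internally consistent rows (the PSA rows of the
source table are known to disagree with their own molecule counts and are
reported, not forced).
"""

import numpy as np

from asdmix import composition_report, enumerate_blends, molecular_mass, recompute_weight_percent
from asdmix.datasets import API_FORMULAS, load_blend_compositions

fla = molecular_mass(API_FORMULAS["FLA"])
pac = molecular_mass(API_FORMULAS["PAC"])
print(f"flufenamic acid  M = {fla:8.2f} amu")
print(f"phenacetin       M = {pac:8.2f} amu\n")

# pure-polymer masses (amu) and chain counts as in the reference systems
polymers = [
    ("EEC", 81913 / 14, 14),
    ("PAA", 80769 / 28, 28),
    ("PSA", 88446 / 12, 12),
    ("PVP", 80061 / 18, 18),
]
blends = enumerate_blends([("FLA", fla), ("PAC", pac)], polymers, [25.0, 40.0])
print(f"enumerated {len(blends)} blends (2 APIs x 4 polymers x 2 loads):")
print(composition_report(blends).round(1).to_string(index=False))

table = load_blend_compositions()
checked = recompute_weight_percent(table, {"FLA": fla, "PAC": pac})
rows = checked[checked["api"].notna() & checked["polymer"].notna()]
good = rows[rows["polymer"].isin(["EEC", "PAA", "PVP"])]
dev = np.abs(good["w_api_recomputed"] - good["w_api_percent"])
print(f"\nmax |recomputed - printed| w(API) on EEC/PAA/PVP rows: {dev.max():.3f} points")
print("PSA rows flagged inconsistent (printed vs recomputed):")
print(
    rows[rows["polymer"] == "PSA"][
        ["api", "n_api", "w_api_percent", "w_api_recomputed", "consistent"]
    ].to_string(index=False)
)
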