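"""Bundled literature reference tables.

Two small tables from a published simulation + stability study of
flufenamic acid (FLA) and phenacetin (PAC) dispersed in four polymers
(Eudragit E copolymer EEC, polyacrylic acid PAA, polystyrene sulfonic acid
PSA, polyvinylpyrrolidone PVP):

* blend compositions — molecule counts, total masses (amu), API weight
  percents and average simulation-cell volumes (nm^3) for the sixteen
  blends and six pure systems;
* stability descriptors — per blend the Coulomb mixing energy (kJ/mol per
  simulation cell), the API diffusion coefficient (1e-10 cm^2/s), the
  heavy-atom RMSF (nm), and the experimental amorphicity indices AI25/AI40
  (0-100, measured at 25 and 40 wt % drug load) plus their mean over
  several loads.

These are *inputs* for the arithmetic, trend and classification analyses:
regenerating them requires microsecond-scale production MD.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_blend_compositions", "load_stability_descriptors", "API_FORMULAS"]

#: molecular formulas of the two drugs in the bundled tables
API_FORMULAS = {"FLA": "C14H10F3NO2", "PAC": "C10H13NO2"}


def _read(name: str) -> pd.DataFrame:
    with resources.files("asdmix.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_blend_compositions() -> pd.DataFrame:
    """Composition table: one row per blend or pure system.

    Columns: polymer, n_chains, monomers_per_chain, api, n_api,
    total_mass_amu, w_api_percent, volume_nm3. Pure-polymer rows have an
    empty ``api``; pure-API rows an empty ``polymer``.
    """
    return _read("blend_compositions.csv")


def load_stability_descriptors() -> pd.DataFrame:
    """Descriptor table: one row per (api, polymer) blend at 40 wt % load.

    Columns: api, polymer, ai25, ai40, ai_mean, delta_ecoul (kJ/mol),
    d (1e-10 cm^2/s), rmsf (nm).
    """
    return _read("stability_descriptors.csv")
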