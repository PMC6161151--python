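"""Mixing energies of blends relative to pure amorphous reference phases.

The mixing energy of a blend is the trajectory-averaged energy of the blend
minus the energy of the same molecules in their pure amorphous phases::

    dE = E_blend - (N_api * e_api_pure + N_pol * e_polymer_pure)

where the pure-phase references are per-molecule (API) and per-chain
(polymer) averages from pure-system trajectories. Three normalizations are
carried: raw (per simulation cell), per sample volume, and per API molecule.
A positive mixing energy favours demixing; a negative one favours the blend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["MixingEnergy", "mixing_energy", "pure_phase_reference", "energy_trend"]

_TERMS = ("e_tot", "e_nb", "e_coul")


@dataclass(frozen=True)
class MixingEnergy:
    """One blend's mixing energy in all three normalizations."""

    term: str  # e_tot | e_nb | e_coul
    delta_raw: float  # kJ/mol per simulation cell
    delta_per_volume: float  # kJ/mol/nm^3
    delta_per_api: float  # kJ/mol per API molecule
    n_api: int
    volume: float  # nm^3
    reference: str = "pure amorphous phases"

    def normalized(self, normalization: str) -> float:
        return {
            "raw": self.delta_raw,
            "per_volume": self.delta_per_volume,
            "per_api": self.delta_per_api,
        }[normalization]


def pure_phase_reference(total_energy: float, n_molecules: int) -> float:
    """Per-molecule (or per-chain) reference energy of a pure phase."""
    if n_molecules <= 0:
        raise ValueError("pure phase must contain at least one molecule")
    return total_energy / n_molecules


def mixing_energy(
    e_blend: float,
    e_api_pure: float,
    e_polymer_pure: float,
    n_api: int,
    n_pol: int,
    volume: float,
    term: str = "e_coul",
) -> MixingEnergy:
    """Assemble a :class:`MixingEnergy` from trajectory-average energies.

    ``e_blend`` is the blend's average energy for ``term`` (whole cell);
    ``e_api_pure``/``e_polymer_pure`` are the pure-phase per-molecule and
    per-chain averages of the *same* term computed with the same method.
    """
    if term not in _TERMS:
        raise ValueError(f"term must be one of {_TERMS}, got {term!r}")
    if volume <= 0:
        raise ValueError("volume must be > 0")
    if n_api < 0 or n_pol < 0:
        raise ValueError("molecule counts must be >= 0")
    delta = e_blend - (n_api * e_api_pure + n_pol * e_polymer_pure)
    return MixingEnergy(
        term=term,
        delta_raw=delta,
        delta_per_volume=delta / volume,
        delta_per_api=delta / n_api if n_api > 0 else math.nan,
        n_api=n_api,
        volume=volume,
    )


def energy_trend(
    blends: dict[str, MixingEnergy],
    rel_tol: float = 1e-9,
) -> list[list[str]]:
    """Rank polymers by mixing energy, ascending (most favourable first).

    Returns tie groups: a list of lists of polymer names; ties (equal
    within ``rel_tol`` relative to the value spread) share a group. The
    ranking must agree across the raw / per-volume / per-API
    normalizations of the stored term; a disagreement (possible when blends
    have very different volumes or API loads) raises ``ValueError``.
    """
    if len(blends) < 2:
        raise ValueError("energy trend needs at least two blends")
    terms = {m.term for m in blends.values()}
    if len(terms) != 1:
        raise ValueError(f"mixing energies carry mixed terms: {sorted(terms)}")

    def order_for(normalization: str) -> list[list[str]]:
        items = [(name, blends[name].normalized(normalization)) for name in blends]
        if any(math.isnan(v) for _, v in items):
            return []
        values = np.array([v for _, v in items])
        scale = max(float(values.max() - values.min()), 1.0)
        items.sort(key=lambda kv: kv[1])
        groups: list[list[str]] = []
        last = None
        for name, value in items:
            if last is None or value - last > rel_tol * scale:
                groups.append([name])
            else:
                groups[-1].append(name)
            last = value
        return [sorted(g) for g in groups]

    orders = {n: order_for(n) for n in ("raw", "per_volume", "per_api")}
    reference = orders["raw"]
    for normalization, order in orders.items():
        if order and order != reference:
            raise ValueError(
                f"polymer ranking differs between raw and {normalization} "
                f"normalization: {reference} vs {order}"
            )
    return reference
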