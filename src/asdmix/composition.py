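"""Blend bookkeeping: molecular masses, molecule counts, API weight percent.

Blends of a small-molecule drug (API) in a polymer matrix are specified by
the number of polymer chains, monomers per chain, and the integer number of
API molecules that brings the API weight fraction closest to a target
(typically 25 or 40 wt %).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import ATOMIC_WEIGHTS

__all__ = [
    "BlendComposition",
    "parse_formula",
    "molecular_mass",
    "api_weight_percent",
    "enumerate_blends",
    "composition_report",
    "recompute_weight_percent",
]

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula ('C14H10F3NO2') into counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def molecular_mass(formula: str | dict[str, int]) -> float:
    """Molecular mass in amu from IUPAC 2021 standard atomic weights."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    mass = 0.0
    for element, count in counts.items():
        if element not in ATOMIC_WEIGHTS:
            raise KeyError(f"unknown element {element!r}")
        if count < 0:
            raise ValueError(f"negative count for element {element!r}")
        mass += count * ATOMIC_WEIGHTS[element]
    return mass


def api_weight_percent(napi: int, api_mass: float, total_mass: float) -> float:
    """API weight percent: 100 * Napi * M_api / total mass."""
    if napi < 0 or api_mass <= 0:
        raise ValueError("napi must be >= 0 and api_mass > 0")
    if total_mass < napi * api_mass:
        raise ValueError(
            f"total mass {total_mass} smaller than API mass {napi * api_mass}"
        )
    if total_mass <= 0:
        raise ValueError("total_mass must be > 0")
    return 100.0 * napi * api_mass / total_mass


@dataclass(frozen=True)
class BlendComposition:
    """Molecular content of one API-polymer blend."""

    polymer_name: str
    n_pol: int
    n_mon: int
    api_name: str
    n_api: int
    api_mass: float  # amu, one API molecule
    polymer_mass: float  # amu, one chain
    volume: float | None = None  # nm^3, trajectory average if known

    def __post_init__(self) -> None:
        if self.n_pol < 0 or self.n_api < 0:
            raise ValueError("molecule counts must be >= 0")
        if self.api_mass <= 0 and self.n_api > 0:
            raise ValueError("api_mass must be > 0")
        if self.polymer_mass <= 0 and self.n_pol > 0:
            raise ValueError("polymer chain mass must be > 0")

    @property
    def total_mass(self) -> float:
        return self.n_api * self.api_mass + self.n_pol * self.polymer_mass

    @property
    def w_api(self) -> float:
        """API concentration in weight percent (0-100)."""
        return api_weight_percent(self.n_api, self.api_mass, self.total_mass)


def enumerate_blends(
    apis: list[tuple[str, float]],
    polymers: list[tuple[str, float, int]],
    target_wt_percents: list[float],
    n_mon: int = 40,
) -> list[BlendComposition]:
    """Cartesian product of APIs x polymers x target weight percents.

    ``apis`` are (name, molecular mass amu); ``polymers`` are
    (name, chain mass amu, number of chains). For each combination the
    integer API count minimizing |w_api - target| is chosen.
    """
    if not apis or not polymers or not target_wt_percents:
        raise ValueError("apis, polymers and targets must be non-empty")
    blends = []
    for api_name, api_mass in apis:
        for pol_name, chain_mass, n_pol in polymers:
            if chain_mass <= 0:
                raise ValueError(f"polymer {pol_name!r} has non-positive chain mass")
            m_pol = n_pol * chain_mass
            for target in target_wt_percents:
                if not (0 <= target < 100):
                    raise ValueError("target weight percent must be in [0, 100)")
                # w(n) = 100 n M / (n M + m_pol); invert and round to nearest
                n_exact = target / (100.0 - target) * m_pol / api_mass
                best = min(
                    (n for n in {int(np.floor(n_exact)), int(np.ceil(n_exact))} if n >= 0),
                    key=lambda n: abs(
                        api_weight_percent(n, api_mass, n * api_mass + m_pol) - target
                    ),
                )
                blends.append(
                    BlendComposition(
                        polymer_name=pol_name,
                        n_pol=n_pol,
                        n_mon=n_mon,
                        api_name=api_name,
                        n_api=best,
                        api_mass=api_mass,
                        polymer_mass=chain_mass,
                    )
                )
    return blends


def composition_report(blends: list[BlendComposition]) -> pd.DataFrame:
    """Composition table: one row per blend with counts, masses, w(API)."""
    return pd.DataFrame(
        {
            "polymer": [b.polymer_name for b in blends],
            "n_chains": [b.n_pol for b in blends],
            "monomers_per_chain": [b.n_mon for b in blends],
            "api": [b.api_name for b in blends],
            "n_api": [b.n_api for b in blends],
            "total_mass_amu": [b.total_mass for b in blends],
            "w_api_percent": [b.w_api for b in blends],
            "volume_nm3": [b.volume for b in blends],
        }
    )


def recompute_weight_percent(
    table: pd.DataFrame,
    api_masses: dict[str, float],
    tolerance: float = 0.1,
) -> pd.DataFrame:
    """Check a printed composition table for internal consistency.

    For every row with an API, recomputes w(API) = 100 * Napi * M_api / m
    from the printed molecule count and total mass and flags rows whose
    printed value deviates by more than ``tolerance`` percentage points.
    Expects columns ``api``, ``n_api``, ``total_mass_amu``,
    ``w_api_percent``. Both values are reported; no agreement is forced.
    """
    out = table.copy()
    recomputed = []
    for _, row in out.iterrows():
        api = row.get("api")
        if isinstance(api, str) and api in api_masses and row["n_api"] > 0:
            recomputed.append(
                api_weight_percent(
                    int(row["n_api"]), api_masses[api], float(row["total_mass_amu"])
                )
            )
        else:
            recomputed.append(np.nan)
    out["w_api_recomputed"] = recomputed
    deviation = np.abs(out["w_api_recomputed"] - out["w_api_percent"])
    out["consistent"] = pd.array(
        [np.nan if np.isnan(d) else d <= tolerance for d in deviation],
        dtype="boolean",
    )
    return out
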