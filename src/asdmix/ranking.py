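"""Descriptor tables, ranges, stability correlations and limiting-factor calls.

The descriptor table joins, per (API, polymer) blend, the thermodynamic
descriptor (Coulomb mixing energy, kJ/mol), the H-bond change, the kinetic
descriptors (translational diffusion coefficient in 1e-10 cm^2/s and the
roto-vibrational RMSF in nm) and the experimental amorphicity indices (AI,
dimensionless 0-100; higher is more stable).

Whether the thermodynamic or the kinetic descriptor is *rate limiting* for
an API's stability ranking is decided from the Spearman rank correlation of
each descriptor with AI at the 40 wt % drug load. Direction matters: a more
negative mixing energy and a lower mobility are the stability-favourable
directions, so only an anti-correlation counts as explanatory power; a
correlation in the physically wrong direction counts as zero. The factor
whose directional strength exceeds the other's by a configurable margin
(default 0.3) is declared rate limiting; otherwise the call is
indeterminate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StabilityRecord",
    "build_descriptor_table",
    "descriptor_range",
    "descriptor_stability_association",
    "classify_limiting_factor",
    "AssociationResult",
]

#: descriptor column -> stability-favourable direction of the raw value
#: (-1: lower value means more stable; these are ranked against AI which
#: increases with stability, so the expected correlation sign is negative)
FAVOURABLE_DIRECTION = {"delta_ecoul": -1, "delta_nhb": +1, "d": -1, "rmsf": -1}


@dataclass(frozen=True)
class StabilityRecord:
    """Experimental amorphicity indices for one blend."""

    api: str
    polymer: str
    ai25: float
    ai40: float
    ai_mean: float

    def __post_init__(self) -> None:
        for v in (self.ai25, self.ai40, self.ai_mean):
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"AI values must be within [0, 100], got {v}")


@dataclass(frozen=True)
class AssociationResult:
    spearman: float
    pearson: float
    n: int
    low_power: bool  # fewer than 3 blends
    undefined: bool  # zero variance in either variable


def build_descriptor_table(
    descriptors: pd.DataFrame, stability: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Join per-blend descriptors with stability records on (api, polymer).

    ``descriptors`` needs columns ``api``, ``polymer`` and one column per
    descriptor (``delta_ecoul``, ``delta_nhb``, ``d``, ``rmsf``, optional
    ``*_std`` replicate spreads); ``stability`` needs ``api``, ``polymer``,
    ``ai25``, ``ai40``, ``ai_mean``. One row per blend is enforced.
    """
    table = descriptors.copy()
    if stability is not None:
        table = table.merge(stability, on=["api", "polymer"], how="left")
    if table.duplicated(["api", "polymer"]).any():
        raise ValueError("descriptor table must have one row per (api, polymer)")
    return table


def _api_rows(table: pd.DataFrame, api: str) -> pd.DataFrame:
    rows = table[table["api"] == api]
    if rows.empty:
        raise KeyError(f"no rows for api {api!r}")
    return rows


def descriptor_range(table: pd.DataFrame, api: str, descriptor: str) -> float:
    """max - min of a descriptor over one API's polymers (same units)."""
    rows = _api_rows(table, api)
    if len(rows) < 2:
        raise ValueError(f"descriptor range needs >= 2 blends for {api!r}")
    values = rows[descriptor].to_numpy(dtype=float)
    if np.any(np.isnan(values)):
        raise ValueError(f"missing {descriptor!r} values for api {api!r}")
    return float(values.max() - values.min())


def descriptor_stability_association(
    table: pd.DataFrame,
    api: str,
    descriptor: str,
    ai_column: str = "ai40",
) -> AssociationResult:
    """Rank (Spearman, mid-ranks for ties) and Pearson correlation between a
    descriptor and the amorphicity index across one API's polymers."""
    rows = _api_rows(table, api)
    x = rows[descriptor].to_numpy(dtype=float)
    y = rows[ai_column].to_numpy(dtype=float)
    low_power = len(x) < 3
    if low_power:
        warnings.warn(
            f"association for {api!r}/{descriptor!r} uses only {len(x)} blends"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return AssociationResult(np.nan, np.nan, len(x), low_power, undefined=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = float(stats.spearmanr(x, y).statistic)
        r = float(stats.pearsonr(x, y).statistic)
    return AssociationResult(rho, r, len(x), low_power, undefined=False)


def _directional_strength(assoc: AssociationResult, descriptor: str) -> float:
    """Explanatory power of a descriptor in its physically favourable
    direction: max(0, expected_sign * rho)."""
    if assoc.undefined:
        return 0.0
    return max(0.0, FAVOURABLE_DIRECTION[descriptor] * assoc.spearman)


def _discriminating(rows: pd.DataFrame, descriptor: str) -> bool:
    """False when every pair of per-polymer values overlaps within 1 std."""
    std_col = f"{descriptor}_std"
    if std_col not in rows.columns or rows[std_col].isna().any():
        warnings.warn(
            f"no replicate spread for {descriptor!r}; skipping overlap screening"
        )
        return True
    vals = rows[descriptor].to_numpy(dtype=float)
    stds = rows[std_col].to_numpy(dtype=float)
    for a, b in combinations(range(len(vals)), 2):
        if abs(vals[a] - vals[b]) > stds[a] + stds[b]:
            return True  # at least one separated pair
    return False


def classify_limiting_factor(
    table: pd.DataFrame,
    api: str,
    energy_descriptor: str = "delta_ecoul",
    mobility_descriptor: str = "d",
    ai_column: str = "ai40",
    threshold: float = 0.3,
) -> str:
    """'thermodynamic' | 'kinetic' | 'indeterminate' for one API.

    Compares the directional Spearman strength of the energy descriptor
    against the mobility descriptor (see module docstring). Descriptors
    whose per-polymer values mutually overlap within one standard deviation
    are treated as non-discriminating (strength 0) when replicate spreads
    are available.
    """
    rows = _api_rows(table, api)
    strengths = {}
    for kind, descriptor in (
        ("thermodynamic", energy_descriptor),
        ("kinetic", mobility_descriptor),
    ):
        assoc = descriptor_stability_association(table, api, descriptor, ai_column)
        strength = _directional_strength(assoc, descriptor)
        if strength > 0 and not _discriminating(rows, descriptor):
            strength = 0.0
        strengths[kind] = strength
    gap = strengths["thermodynamic"] - strengths["kinetic"]
    if gap >= threshold:
        return "thermodynamic"
    if gap <= -threshold:
        return "kinetic"
    return "indeterminate"
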