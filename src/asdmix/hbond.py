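"""Geometric hydrogen-bond detection and the change in H-bond count on mixing.

A hydrogen bond is reported when the donor-acceptor distance (minimum image)
is at most ``d_cut`` (default 0.35 nm) and the hydrogen-donor-acceptor angle
— measured at the **donor** heavy atom, between the D->H and D->A vectors —
is at most ``a_cut`` (default 30 degrees). These are the defaults of the
standard trajectory-analysis H-bond tool; both are configurable. Note the
angle convention: some tools use the angle at the hydrogen instead.

Donors are O/N heavy atoms with a covalently bound hydrogen flagged
``is_donor_h``; acceptors are atoms flagged ``is_acceptor`` (O/N by
convention; fluorine is not an acceptor by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .model import Frame, SystemTopology, Trajectory

__all__ = [
    "HBond",
    "CorrelationResult",
    "find_hbonds",
    "count_hbonds",
    "average_hbond_count",
    "delta_nhb",
    "pearson_correlation",
]


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float  # donor-acceptor, nm
    angle: float  # hydrogen-donor-acceptor, degrees
    intramolecular: bool
    species_pair: str  # e.g. "api-polymer"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"Pearson r out of range: {self.r}")


def _donor_pairs(topology: SystemTopology) -> list[tuple[int, int]]:
    """(donor heavy atom, hydrogen) global index pairs from the bond graph."""
    pairs: list[tuple[int, int]] = []
    offset = 0
    for mol, count in topology.molecules:
        local: list[tuple[int, int]] = []
        for b in mol.bonds:
            for h, d in ((b.i, b.j), (b.j, b.i)):
                if mol.atoms[h].is_donor_h and mol.atoms[d].element in ("N", "O"):
                    local.append((d, h))
        for _ in range(count):
            pairs.extend((offset + d, offset + h) for d, h in local)
            offset += mol.n_atoms
    return pairs


def find_hbonds(
    frame: Frame,
    topology: SystemTopology,
    d_cut: float = 0.35,
    a_cut: float = 30.0,
) -> list[HBond]:
    """All hydrogen bonds in one frame passing the geometric criterion."""
    frame.validate_against(topology)
    coords = frame.coordinates
    box = frame.box
    donors = _donor_pairs(topology)
    acceptors = np.flatnonzero(topology.is_acceptor)
    if not donors or not len(acceptors):
        return []
    bonds: list[HBond] = []
    acc_pos = coords[acceptors]
    for d_idx, h_idx in donors:
        da = acc_pos - coords[d_idx]
        if box is not None:
            da -= box * np.round(da / box)
        dist = np.linalg.norm(da, axis=1)
        dh = coords[h_idx] - coords[d_idx]
        if box is not None:
            dh -= box * np.round(dh / box)
        n_dh = np.linalg.norm(dh)
        for k in np.flatnonzero((dist <= d_cut) & (dist > 1e-9)):
            a_idx = int(acceptors[k])
            if a_idx == d_idx:
                continue
            cos_t = float(np.clip(da[k] @ dh / (dist[k] * n_dh), -1.0, 1.0))
            angle = math.degrees(math.acos(cos_t))
            if angle <= a_cut:
                mol_d = topology.atom_molecule[d_idx]
                mol_a = topology.atom_molecule[a_idx]
                roles = sorted(
                    (topology.instances[mol_d].role, topology.instances[mol_a].role)
                )
                bonds.append(
                    HBond(
                        donor=d_idx,
                        hydrogen=h_idx,
                        acceptor=a_idx,
                        distance=float(dist[k]),
                        angle=angle,
                        intramolecular=bool(mol_d == mol_a),
                        species_pair="-".join(roles),
                    )
                )
    return bonds


def count_hbonds(
    frame: Frame,
    topology: SystemTopology,
    d_cut: float = 0.35,
    a_cut: float = 30.0,
    by_species: bool = False,
):
    """H-bond count in one frame; with ``by_species`` a dict per role pair."""
    bonds = find_hbonds(frame, topology, d_cut, a_cut)
    if not by_species:
        return len(bonds)
    counts: dict[str, int] = {}
    for b in bonds:
        counts[b.species_pair] = counts.get(b.species_pair, 0) + 1
    return counts


def average_hbond_count(
    traj: Trajectory | Sequence[Frame],
    topology: SystemTopology,
    d_cut: float = 0.35,
    a_cut: float = 30.0,
) -> float:
    frames = list(traj)
    return float(
        np.mean([count_hbonds(f, topology, d_cut, a_cut) for f in frames])
    )


def delta_nhb(
    blend_traj: Trajectory | Sequence[Frame],
    pure_api_traj: Trajectory | Sequence[Frame],
    pure_polymer_traj: Trajectory | Sequence[Frame],
    blend_topology: SystemTopology,
    pure_api_topology: SystemTopology,
    pure_polymer_topology: SystemTopology,
    d_cut: float = 0.35,
    a_cut: float = 30.0,
) -> float:
    """Change in average H-bond count on mixing.

    The pure-phase counts are scaled to the blend's molecule numbers:
    dNHB = <N_blend> - (<N_pure_api> * Napi_blend / Napi_pure
                        + <N_pure_pol> * Npol_blend / Npol_pure).
    A positive value means mixing creates hydrogen bonds.
    """

    def total_count(topology: SystemTopology, role: str) -> int:
        return sum(c for mol, c in topology.molecules if topology.roles[mol.name] == role)

    n_api_blend = total_count(blend_topology, "api")
    n_pol_blend = total_count(blend_topology, "polymer")
    n_api_pure = total_count(pure_api_topology, "api")
    n_pol_pure = total_count(pure_polymer_topology, "polymer")
    if n_api_blend and not n_api_pure:
        raise ValueError("blend contains API but pure-API topology has none")
    if n_pol_blend and not n_pol_pure:
        raise ValueError("blend contains polymer but pure-polymer topology has none")
    n_blend = average_hbond_count(blend_traj, blend_topology, d_cut, a_cut)
    n_api = average_hbond_count(pure_api_traj, pure_api_topology, d_cut, a_cut)
    n_pol = average_hbond_count(pure_polymer_traj, pure_polymer_topology, d_cut, a_cut)
    scaled = 0.0
    if n_api_pure:
        scaled += n_api * n_api_blend / n_api_pure
    if n_pol_pure:
        scaled += n_pol * n_pol_blend / n_pol_pure
    return n_blend - scaled


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation; requires n >= 3 and nonzero variance."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-d sequences of equal length")
    if len(xa) < 3:
        raise ValueError("Pearson correlation needs at least 3 points")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("Pearson correlation undefined: zero variance")
    r = float(stats.pearsonr(xa, ya).statistic)
    return CorrelationResult(r=r, n=len(xa))
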