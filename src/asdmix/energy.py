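"""Force-field energy evaluation and intermolecular Coulomb decomposition.

The potential energy of a configuration is split in the classical
fixed-charge force-field way::

    E_tot = E_bond + E_angle + E_dih + E_LJ + E_Coul

with harmonic bonds and angles, periodic-cosine dihedrals, Lennard-Jones
dispersion/repulsion and point-charge electrostatics. Non-bonded terms skip
atom pairs separated by one or two bonds; 1-4 pairs (three bonds apart) are
scaled by the Amber convention (LJ / 2, Coulomb / 1.2) inside ``e_tot`` and
excluded entirely from the intermolecular descriptor ``e_nb``.

Electrostatics supports three routes: a non-periodic direct sum, a periodic
minimum-image sum with cutoff, and classic Ewald summation (real +
reciprocal + self + exclusion corrections) converged to a target relative
accuracy — the analysis-grade equivalent of the mesh Ewald used by MD
engines.

The centrepiece is :func:`intermolecular_coulomb_by_zeroing`: because the
Coulomb energy is a quadratic form in the charges, the interaction of one
molecule with the rest of the system is extracted *exactly* — for any of the
three methods, including the long-range Ewald part — by evaluating the
energy three times (full system; charges of the molecule zeroed; all other
charges zeroed) and forming ``E_full - E_without - E_only``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf, erfc

from .constants import COULOMB_CONSTANT, FUDGE_LJ, FUDGE_QQ
from .model import Frame, SystemTopology, Trajectory

_OVERLAP_NM = 1e-6

__all__ = [
    "EnergyBreakdown",
    "EwaldParams",
    "lj_energy",
    "coulomb_energy",
    "bonded_energy",
    "total_energy",
    "intermolecular_coulomb_by_zeroing",
    "species_intermolecular_coulomb",
]


@dataclass(frozen=True)
class EwaldParams:
    """Classic-Ewald control parameters.

    ``accuracy`` is the target relative truncation error; the splitting
    parameter and reciprocal-space extent are derived from it unless given
    explicitly. ``alpha`` is in nm^-1, ``cutoff`` in nm.
    """

    cutoff: float = 0.9
    accuracy: float = 1e-5
    alpha: float | None = None
    kmax: int | None = None

    def resolve(self, box: np.ndarray) -> tuple[float, np.ndarray]:
        if self.cutoff > 0.5 * float(np.min(box)) + 1e-12:
            raise ValueError(
                f"Ewald real-space cutoff {self.cutoff} nm exceeds half the "
                f"smallest box edge ({0.5 * float(np.min(box)):.4f} nm)"
            )
        s = math.sqrt(-math.log(self.accuracy))
        alpha = self.alpha if self.alpha is not None else s / self.cutoff
        if self.kmax is not None:
            nmax = np.full(3, self.kmax, dtype=int)
        else:
            nmax = np.ceil(alpha * box * s / math.pi).astype(int)
        return alpha, np.maximum(nmax, 1)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-term energies of one configuration, kJ/mol.

    ``e_lj``/``e_coul`` include the scaled 1-4 contributions so that
    ``e_tot`` is their sum with the bonded terms; ``e_nb`` is the
    intermolecular-quality non-bonded sum (no 1-4 at all).
    """

    e_bond: float
    e_angle: float
    e_dih: float
    e_lj: float
    e_coul: float
    e_nb: float
    coulomb_method: str

    @property
    def e_tot(self) -> float:
        return self.e_bond + self.e_angle + self.e_dih + self.e_lj + self.e_coul


# ---------------------------------------------------------------------------
# geometry helpers


def _displacements(coords: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    d = coords[:, None, :] - coords[None, :, :]
    if box is not None:
        d -= box * np.round(d / box)
    return d


def _distance_matrix(coords: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    return np.linalg.norm(_displacements(coords, box), axis=-1)


def _check_cutoff(cutoff: float | None, box: np.ndarray | None) -> None:
    if cutoff is not None and box is not None:
        if cutoff > 0.5 * float(np.min(box)) + 1e-12:
            raise ValueError(
                f"cutoff {cutoff} nm exceeds half the smallest box edge "
                f"({0.5 * float(np.min(box)):.4f} nm)"
            )


def _pair_mask(
    topology: SystemTopology,
    r: np.ndarray,
    cutoff: float | None,
) -> np.ndarray:
    """Upper-triangle mask of interacting (non-excluded) pairs."""
    mask = np.triu(np.ones_like(r, dtype=bool), k=1)
    mask &= ~topology.exclusion_mask()
    if cutoff is not None:
        mask &= r <= cutoff
    return mask


# ---------------------------------------------------------------------------
# Lennard-Jones


def lj_energy(
    frame: Frame,
    topology: SystemTopology,
    cutoff: float | None = 0.9,
    tail_correction: bool = False,
) -> float:
    """Lennard-Jones energy over non-excluded pairs (kJ/mol).

    Lorentz-Berthelot combining rules; minimum-image convention when the
    frame has a box; optional isotropic long-range dispersion correction
    beyond the cutoff (uniform-density approximation, negative for
    attractive systems).
    """
    frame.validate_against(topology)
    box = frame.box
    _check_cutoff(cutoff, box)
    r = _distance_matrix(frame.coordinates, box)
    mask = _pair_mask(topology, r, cutoff)
    sig = 0.5 * (topology.lj_sigma[:, None] + topology.lj_sigma[None, :])
    eps = np.sqrt(topology.lj_epsilon[:, None] * topology.lj_epsilon[None, :])
    mask = mask & (eps > 0)
    rr = r[mask]
    if np.any(rr < _OVERLAP_NM):
        raise ValueError("overlapping atoms (r < 1e-6 nm) in LJ evaluation")
    sr6 = (sig[mask] / rr) ** 6
    energy = float(np.sum(4.0 * eps[mask] * (sr6 * sr6 - sr6)))
    if tail_correction:
        if box is None or cutoff is None:
            raise ValueError("tail correction requires a periodic box and a cutoff")
        energy += _lj_tail(topology, float(np.prod(box)), cutoff)
    return energy


def _lj_tail(topology: SystemTopology, volume: float, cutoff: float) -> float:
    """Standard isotropic dispersion tail: sum over atom-type pairs of
    (8 pi N_a N_b eps sigma^3 / 3 V) [ (sigma/rc)^9 / 3 - (sigma/rc)^3 ]."""
    types, counts = np.unique(
        np.stack([topology.lj_sigma, topology.lj_epsilon], axis=1),
        axis=0,
        return_counts=True,
    )
    total = 0.0
    for (s_a, e_a), n_a in zip(types, counts):
        for (s_b, e_b), n_b in zip(types, counts):
            eps = math.sqrt(e_a * e_b)
            if eps == 0.0:
                continue
            sig = 0.5 * (s_a + s_b)
            x3 = (sig / cutoff) ** 3
            total += (
                0.5
                * n_a
                * n_b
                * (16.0 * math.pi / volume)
                * eps
                * sig**3
                * (x3**3 / 9.0 - x3 / 3.0)
            )
    return total


# ---------------------------------------------------------------------------
# Coulomb


def coulomb_energy(
    frame: Frame,
    topology: SystemTopology,
    method: str = "direct",
    cutoff: float | None = 0.9,
    ewald: EwaldParams | None = None,
    charges: np.ndarray | None = None,
) -> float:
    """Point-charge Coulomb energy over non-excluded pairs (kJ/mol).

    method:
      * ``direct`` — non-periodic all-pairs sum (no cutoff).
      * ``minimum-image`` — periodic nearest image with ``cutoff``.
      * ``ewald`` — classic Ewald summation; a non-neutral charge set is
        handled with the uniform background-charge correction and a warning.

    ``charges`` overrides the topology charges (used by the charge-zeroing
    decomposition); shape (n_atoms,).
    """
    frame.validate_against(topology)
    q = topology.charges if charges is None else np.asarray(charges, dtype=float)
    if q.shape != (topology.n_atoms,):
        raise ValueError("charge override must have one value per atom")
    if not np.any(q):
        return 0.0
    if method == "direct":
        return _coulomb_pairwise(frame, topology, q, box=None, cutoff=None)
    if method == "minimum-image":
        if frame.box is None:
            raise ValueError("minimum-image Coulomb requires a periodic box")
        _check_cutoff(cutoff, frame.box)
        return _coulomb_pairwise(frame, topology, q, box=frame.box, cutoff=cutoff)
    if method == "ewald":
        if frame.box is None:
            raise ValueError("Ewald summation requires a periodic box")
        return _coulomb_ewald(frame, topology, q, ewald or EwaldParams())
    raise ValueError(f"unknown Coulomb method {method!r}")


def _coulomb_pairwise(
    frame: Frame,
    topology: SystemTopology,
    q: np.ndarray,
    box: np.ndarray | None,
    cutoff: float | None,
) -> float:
    r = _distance_matrix(frame.coordinates, box)
    mask = _pair_mask(topology, r, cutoff)
    qq = q[:, None] * q[None, :]
    mask = mask & (qq != 0.0)
    rr = r[mask]
    if np.any(rr < _OVERLAP_NM):
        raise ValueError("overlapping charged atoms (r < 1e-6 nm)")
    return float(COULOMB_CONSTANT * np.sum(qq[mask] / rr))


def _coulomb_ewald(
    frame: Frame, topology: SystemTopology, q: np.ndarray, params: EwaldParams
) -> float:
    box = frame.box
    coords = frame.coordinates
    alpha, nmax = params.resolve(box)
    volume = float(np.prod(box))
    net = float(q.sum())

    # real space: erfc-screened sum over non-excluded minimum-image pairs
    r = _distance_matrix(coords, box)
    mask = _pair_mask(topology, r, params.cutoff)
    qq = q[:, None] * q[None, :]
    mask = mask & (qq != 0.0)
    rr = r[mask]
    if np.any(rr < _OVERLAP_NM):
        raise ValueError("overlapping charged atoms (r < 1e-6 nm)")
    e_real = float(np.sum(qq[mask] * erfc(alpha * rr) / rr))

    # reciprocal space over all k != 0 within the truncation ellipsoid
    nx = np.arange(-nmax[0], nmax[0] + 1)
    ny = np.arange(-nmax[1], nmax[1] + 1)
    nz = np.arange(-nmax[2], nmax[2] + 1)
    grid = np.stack(np.meshgrid(nx, ny, nz, indexing="ij"), axis=-1).reshape(-1, 3)
    grid = grid[np.any(grid != 0, axis=1)]
    k = 2.0 * math.pi * grid / box  # (n_k, 3)
    k2 = np.einsum("ij,ij->i", k, k)
    kcut2 = 4.0 * alpha * alpha * (-math.log(params.accuracy))
    keep = k2 <= kcut2
    k, k2 = k[keep], k2[keep]
    phases = coords @ k.T  # (n_atoms, n_k)
    s_re = q @ np.cos(phases)
    s_im = q @ np.sin(phases)
    e_recip = float(
        (2.0 * math.pi / volume)
        * np.sum(np.exp(-k2 / (4.0 * alpha * alpha)) / k2 * (s_re**2 + s_im**2))
    )

    e_self = -alpha / math.sqrt(math.pi) * float(np.sum(q * q))

    # excluded intramolecular pairs: remove their reciprocal-space part
    e_excl = 0.0
    ep = topology.excluded_pairs
    if len(ep):
        qq_ep = q[ep[:, 0]] * q[ep[:, 1]]
        live = qq_ep != 0.0
        if np.any(live):
            d = coords[ep[live, 0]] - coords[ep[live, 1]]
            d -= box * np.round(d / box)
            r_ep = np.linalg.norm(d, axis=1)
            if np.any(r_ep < _OVERLAP_NM):
                raise ValueError("overlapping excluded charged pair")
            e_excl = -float(np.sum(qq_ep[live] * erf(alpha * r_ep) / r_ep))

    e_background = 0.0
    if abs(net) > 1e-8:
        warnings.warn(
            f"Ewald sum on a non-neutral system (net charge {net:.3g} e); "
            "applying uniform background-charge correction",
            stacklevel=3,
        )
    e_background = -math.pi * net * net / (2.0 * alpha * alpha * volume)

    return COULOMB_CONSTANT * (e_real + e_recip + e_self + e_excl + e_background)


# ---------------------------------------------------------------------------
# bonded terms


def _minimum_image(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is not None:
        d = d - box * np.round(d / box)
    return d


def bonded_energy(frame: Frame, topology: SystemTopology) -> tuple[float, float, float]:
    """(e_bond, e_angle, e_dih) in kJ/mol.

    Harmonic bonds 1/2 k (r - r0)^2, harmonic angles 1/2 k (theta - theta0)^2,
    periodic dihedrals k (1 + cos(n phi - phase)).
    """
    frame.validate_against(topology)
    coords = frame.coordinates
    box = frame.box
    e_bond = e_angle = e_dih = 0.0
    offset = 0
    for mol, count in topology.molecules:
        for _ in range(count):
            for b in mol.bonds:
                d = _minimum_image(coords[offset + b.i] - coords[offset + b.j], box)
                r = float(np.linalg.norm(d))
                e_bond += 0.5 * b.k * (r - b.r0) ** 2
            for a in mol.angles:
                u = _minimum_image(coords[offset + a.i] - coords[offset + a.j], box)
                w = _minimum_image(coords[offset + a.k] - coords[offset + a.j], box)
                nu, nw = np.linalg.norm(u), np.linalg.norm(w)
                if nu < _OVERLAP_NM or nw < _OVERLAP_NM:
                    raise ValueError("zero-length bond vector in angle evaluation")
                cos_t = float(np.clip(u @ w / (nu * nw), -1.0, 1.0))
                e_angle += 0.5 * a.k_theta * (math.acos(cos_t) - a.theta0) ** 2
            for d4 in mol.dihedrals:
                phi = _dihedral_angle(
                    coords[offset + d4.i],
                    coords[offset + d4.j],
                    coords[offset + d4.k],
                    coords[offset + d4.l],
                    box,
                )
                e_dih += d4.k_phi * (1.0 + math.cos(d4.periodicity * phi - d4.phase))
            offset += mol.n_atoms
    return e_bond, e_angle, e_dih


def _dihedral_angle(p0, p1, p2, p3, box) -> float:
    b1 = _minimum_image(p1 - p0, box)
    b2 = _minimum_image(p2 - p1, box)
    b3 = _minimum_image(p3 - p2, box)
    n2 = np.linalg.norm(b2)
    if n2 < _OVERLAP_NM:
        raise ValueError("zero-length bond vector in dihedral evaluation")
    c1 = np.cross(b1, b2)
    c2 = np.cross(b2, b3)
    x = float(c1 @ c2)
    y = float(np.cross(c1, c2) @ b2 / n2)
    return math.atan2(y, x)


# ---------------------------------------------------------------------------
# assembled breakdown


def _pair_term_14(
    frame: Frame, topology: SystemTopology, q: np.ndarray | None = None
) -> tuple[float, float]:
    """Unscaled (lj_14, coul_14) over 1-4 pairs at nearest image."""
    pairs = topology.pairs_14
    if not len(pairs):
        return 0.0, 0.0
    d = frame.coordinates[pairs[:, 0]] - frame.coordinates[pairs[:, 1]]
    d = _minimum_image(d, frame.box)
    r = np.linalg.norm(d, axis=1)
    if np.any(r < _OVERLAP_NM):
        raise ValueError("overlapping 1-4 pair")
    sig = 0.5 * (topology.lj_sigma[pairs[:, 0]] + topology.lj_sigma[pairs[:, 1]])
    eps = np.sqrt(topology.lj_epsilon[pairs[:, 0]] * topology.lj_epsilon[pairs[:, 1]])
    sr6 = np.where(eps > 0, (sig / r) ** 6, 0.0)
    lj14 = float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)))
    qv = topology.charges if q is None else q
    coul14 = float(COULOMB_CONSTANT * np.sum(qv[pairs[:, 0]] * qv[pairs[:, 1]] / r))
    return lj14, coul14


def total_energy(
    frame: Frame,
    topology: SystemTopology,
    coulomb_method: str = "direct",
    cutoff: float | None = 0.9,
    tail_correction: bool = False,
    ewald: EwaldParams | None = None,
) -> EnergyBreakdown:
    """Assemble the full energy breakdown of one configuration."""
    e_bond, e_angle, e_dih = bonded_energy(frame, topology)
    lj_cut = None if coulomb_method == "direct" and frame.box is None else cutoff
    lj_nb = lj_energy(frame, topology, cutoff=lj_cut, tail_correction=tail_correction)
    coul_nb = coulomb_energy(
        frame, topology, method=coulomb_method, cutoff=cutoff, ewald=ewald
    )
    lj14, coul14 = _pair_term_14(frame, topology)
    return EnergyBreakdown(
        e_bond=e_bond,
        e_angle=e_angle,
        e_dih=e_dih,
        e_lj=lj_nb + FUDGE_LJ * lj14,
        e_coul=coul_nb + FUDGE_QQ * coul14,
        e_nb=lj_nb + coul_nb,
        coulomb_method=coulomb_method,
    )


# ---------------------------------------------------------------------------
# charge-zeroing intermolecular Coulomb decomposition


def _frames_of(traj: Trajectory | Frame | Sequence[Frame]) -> Iterable[Frame]:
    if isinstance(traj, Frame):
        return (traj,)
    return traj


def _zeroing_cross_energy(
    frame: Frame,
    topology: SystemTopology,
    member_mask: np.ndarray,
    method: str,
    cutoff: float | None,
    ewald: EwaldParams | None,
) -> float:
    """E_cross of the atom set ``member_mask`` with the rest of the system,
    via the threefold charge-zeroing re-evaluation."""
    q = topology.charges

    def energy(charge_set: np.ndarray) -> float:
        with warnings.catch_warnings():
            # zeroed subsystems are legitimately non-neutral under Ewald
            warnings.simplefilter("ignore")
            return coulomb_energy(
                frame, topology, method=method, cutoff=cutoff, ewald=ewald,
                charges=charge_set,
            )

    e_full = energy(q)
    e_without = energy(np.where(member_mask, 0.0, q))
    e_only = energy(np.where(member_mask, q, 0.0))
    return e_full - e_without - e_only


def intermolecular_coulomb_by_zeroing(
    traj: Trajectory | Frame,
    topology: SystemTopology,
    molecule_instance: int,
    method: str = "direct",
    cutoff: float | None = 0.9,
    ewald: EwaldParams | None = None,
) -> float:
    """Trajectory-averaged Coulomb interaction of one molecule with all
    others (kJ/mol), by threefold charge-zeroing re-evaluation.

    Exact for any Coulomb method that is quadratic in the charges — which
    covers direct, minimum-image and Ewald (the background term included).
    """
    if not (0 <= molecule_instance < len(topology.instances)):
        raise IndexError(
            f"molecule instance {molecule_instance} out of range "
            f"(system has {len(topology.instances)} molecules)"
        )
    member = topology.atom_molecule == molecule_instance
    values = [
        _zeroing_cross_energy(f, topology, member, method, cutoff, ewald)
        for f in _frames_of(traj)
    ]
    return float(np.mean(values))


def species_intermolecular_coulomb(
    traj: Trajectory | Frame,
    topology: SystemTopology,
    species: str,
    method: str = "direct",
    cutoff: float | None = 0.9,
    ewald: EwaldParams | None = None,
) -> float:
    """System-level intermolecular Coulomb energy involving ``species``
    (kJ/mol, trajectory-averaged), without double counting.

    Applies the charge-zeroing decomposition to each molecule of the species
    in turn; summing those cross energies counts every within-species
    molecule pair twice, so the within-species intermolecular energy
    (obtained from one further zeroing pass on the whole species) is
    subtracted once. For a one-species system this is the total
    intermolecular Coulomb energy of the system.
    """
    instances = topology.instances_of(species)
    per_frame: list[float] = []
    for frame in _frames_of(traj):
        total_cross = sum(
            _zeroing_cross_energy(
                frame,
                topology,
                topology.atom_molecule == inst.index,
                method,
                cutoff,
                ewald,
            )
            for inst in instances
        )
        species_mask = np.isin(
            topology.atom_molecule, [inst.index for inst in instances]
        )

        def energy(charge_set: np.ndarray) -> float:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return coulomb_energy(
                    frame, topology, method=method, cutoff=cutoff, ewald=ewald,
                    charges=charge_set,
                )

        q = topology.charges
        e_only_species = energy(np.where(species_mask, q, 0.0))
        e_intra = sum(
            energy(np.where(topology.atom_molecule == inst.index, q, 0.0))
            for inst in instances
        )
        e_within = e_only_species - e_intra
        per_frame.append(total_cross - e_within)
    return float(np.mean(per_frame))
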