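"""Synthetic systems with known ground truth for every analysis stage.

These generators stand in for MD production runs: each one produces a
(:class:`SystemTopology`, :class:`Trajectory`) pair whose target property is
known exactly, so the analysis code can be validated as parameter recovery.

* :func:`gen_brownian` — point molecules taking i.i.d. Gaussian steps with
  per-axis variance ``2 D dt`` (exact Brownian sampling, no integrator
  error); the MSD analysis must recover ``D``.
* :func:`gen_harmonic` — atoms drawn i.i.d. around fixed sites with per-axis
  variance ``kT/k``; the RMSF must recover ``sqrt(3 kT / k)`` (equipartition
  in an isotropic harmonic well).
* :func:`gen_hbond_fixture` — donor-H...acceptor triples placed at exactly
  requested distance/angle geometries.
* :func:`gen_rock_salt` / :func:`gen_lj_lattice` — small charged / LJ
  lattices with analytically or brute-force computable energies.
* :func:`gen_toy_blend` — a packed periodic drug-polymer toy with four
  replicate trajectories, mirroring the replicate structure of production
  studies (four independent runs per blend).

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import AtomSpec, Bond, Frame, MoleculeTopology, SystemTopology, Trajectory

__all__ = [
    "GeneratorSpec",
    "generate",
    "gen_brownian",
    "gen_harmonic",
    "gen_hbond_fixture",
    "gen_rock_salt",
    "gen_lj_lattice",
    "gen_toy_blend",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative generator request: kind, parameters, seed."""

    kind: str  # brownian | harmonic | hbond_fixture | rock_salt | lj_lattice | toy_blend
    parameters: dict = field(default_factory=dict)
    seed: int = 0


def generate(spec: GeneratorSpec):
    """Dispatch a :class:`GeneratorSpec` to the matching generator."""
    table = {
        "brownian": gen_brownian,
        "harmonic": gen_harmonic,
        "hbond_fixture": gen_hbond_fixture,
        "rock_salt": gen_rock_salt,
        "lj_lattice": gen_lj_lattice,
        "toy_blend": gen_toy_blend,
    }
    if spec.kind not in table:
        raise ValueError(f"unknown generator kind {spec.kind!r}")
    kwargs = dict(spec.parameters)
    if spec.kind not in ("hbond_fixture", "rock_salt", "lj_lattice"):
        kwargs.setdefault("seed", spec.seed)
    return table[spec.kind](**kwargs)


def _grid_points(n: int, box: float, rng: np.random.Generator | None = None) -> np.ndarray:
    """n points on a cubic grid inside a box of edge ``box``."""
    side = math.ceil(n ** (1.0 / 3.0))
    spacing = box / side
    pts = np.stack(
        np.meshgrid(*[np.arange(side)] * 3, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    if rng is not None:
        rng.shuffle(pts)
    return (pts[:n] + 0.5) * spacing


def gen_brownian(
    n_mol: int = 95,
    d: float = 1e-8,
    dt: float = 2.0,
    n_frames: int = 10_000,
    box: float = 10.0,
    seed: int = 0,
) -> tuple[SystemTopology, Trajectory]:
    """Brownian point molecules with prescribed diffusion coefficient.

    ``d`` is in nm^2/ps (1e-8 nm^2/ps corresponds to 1e-10 cm^2/s, the
    output unit of the diffusion analysis); steps are exact Gaussian draws
    with per-axis variance ``2 d dt``. Coordinates are stored unwrapped.
    ``d = 0`` yields a static trajectory; negative values are rejected.
    """
    if d < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    if n_frames < 2 or dt <= 0 or n_mol < 1:
        raise ValueError("need n_frames >= 2, dt > 0, n_mol >= 1")
    rng = np.random.default_rng(seed)
    mol = MoleculeTopology("particle", [AtomSpec("P", "C", mass=1.0)])
    top = SystemTopology([(mol, n_mol)], roles={"particle": "api"})
    start = _grid_points(n_mol, box)
    steps = rng.normal(0.0, math.sqrt(2.0 * d * dt), size=(n_frames - 1, n_mol, 3))
    coords = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    frames = [
        Frame(coords[t], box=np.full(3, box), time=t * dt, wrapped=False)
        for t in range(n_frames)
    ]
    return top, Trajectory(frames)


def gen_harmonic(
    n_atoms_per_mol: int = 5,
    n_mol: int = 20,
    k: float = 1000.0,
    kt: float = 2.494,
    n_frames: int = 10_000,
    dt: float = 2.0,
    seed: int = 0,
    drift: float = 0.0,
) -> tuple[SystemTopology, Trajectory]:
    """Atoms fluctuating in isotropic harmonic wells of stiffness ``k``.

    Fluctuations are sampled in the molecular centre-of-mass frame — the
    frame the RMSF analysis works in after per-molecule COM removal — as
    Gaussian displacements about fixed sites with per-axis variance
    ``kt / k`` (kT in kJ/mol, k in kJ/mol/nm^2), so the exact per-atom RMSF
    is sqrt(3 kt / k). Sampling directly in the COM frame keeps the
    equipartition closed form exact: i.i.d. lab-frame draws would lose a
    factor sqrt(1 - 1/n_atoms) to the COM projection. ``drift`` adds a
    rigid translation (nm per frame) to every atom, which the COM removal
    must cancel. All atoms share one mass, so the mass-weighted COM is the
    arithmetic mean.
    """
    if k <= 0:
        raise ValueError("spring constant k must be > 0")
    if kt < 0:
        raise ValueError("kT must be >= 0")
    if n_frames < 2:
        raise ValueError("need n_frames >= 2")
    if n_atoms_per_mol < 2:
        raise ValueError("COM-frame sampling needs >= 2 atoms per molecule")
    rng = np.random.default_rng(seed)
    atoms = [AtomSpec(f"C{i + 1}", "C", mass=12.011) for i in range(n_atoms_per_mol)]
    mol = MoleculeTopology("blob", atoms)
    top = SystemTopology([(mol, n_mol)], roles={"blob": "api"})
    box = 10.0 * max(1, round(n_mol ** (1 / 3) + 1))
    centres = _grid_points(n_mol, box)
    sites = centres[:, None, :] + rng.normal(0.0, 0.3, size=(n_mol, n_atoms_per_mol, 3))
    sites = sites.reshape(-1, 3)
    sigma = math.sqrt(kt / k)
    raw = rng.normal(0.0, sigma, size=(n_frames, n_mol, n_atoms_per_mol, 3))
    # project onto the zero-COM subspace, rescaled to keep per-axis variance
    raw -= raw.mean(axis=2, keepdims=True)
    if n_atoms_per_mol > 1:
        raw /= math.sqrt(1.0 - 1.0 / n_atoms_per_mol)
    noise = raw.reshape(n_frames, n_mol * n_atoms_per_mol, 3)
    shift = drift * np.arange(n_frames)[:, None, None] * np.array([1.0, 0.0, 0.0])
    coords = sites[None] + noise + shift
    frames = [
        Frame(coords[t], box=np.full(3, box), time=t * dt, wrapped=False)
        for t in range(n_frames)
    ]
    return top, Trajectory(frames)


_OH_BOND = 0.096  # covalent O-H length, nm


def gen_hbond_fixture(
    geometries: Sequence[tuple[float, float]],
    box: float = 20.0,
) -> tuple[SystemTopology, Frame]:
    """Donor-H...acceptor triples at exactly requested geometries.

    Each entry is (donor-acceptor distance nm, hydrogen-donor-acceptor angle
    in degrees, measured at the donor). Every triple is placed far from the
    others so counts equal the number of geometries passing the criterion.
    """
    if not geometries:
        raise ValueError("need at least one (distance, angle) entry")
    donor = MoleculeTopology(
        "donor",
        [
            AtomSpec("O1", "O", mass=15.999, charge=-0.4, is_acceptor=True),
            AtomSpec("H1", "H", mass=1.008, charge=0.4, is_donor_h=True),
        ],
        bonds=[Bond(0, 1, r0=_OH_BOND, k=3.0e5)],
    )
    acceptor = MoleculeTopology(
        "acceptor", [AtomSpec("O2", "O", mass=15.999, is_acceptor=True)]
    )
    n = len(geometries)
    coords = []
    spacing = 4.0  # nm; far beyond any H-bond cutoff
    for idx, (dist, angle_deg) in enumerate(geometries):
        if dist < _OH_BOND:
            raise ValueError(
                f"donor-acceptor distance {dist} nm below the covalent O-H length"
            )
        origin = np.array([2.0 + spacing * idx, 2.0, 2.0])
        theta = math.radians(angle_deg)
        coords.append([origin, origin + np.array([_OH_BOND, 0.0, 0.0])])
        coords.append(
            [origin + dist * np.array([math.cos(theta), math.sin(theta), 0.0])]
        )
    donor_coords = [c for pair in coords[0::2] for c in pair]
    acceptor_coords = [c for single in coords[1::2] for c in single]
    top = SystemTopology(
        [(donor, n), (acceptor, n)], roles={"donor": "api", "acceptor": "polymer"}
    )
    all_coords = np.asarray(donor_coords + acceptor_coords)
    edge = max(box, spacing * n + 4.0)
    return top, Frame(all_coords, box=np.full(3, edge), wrapped=False)


def gen_rock_salt(
    n_cells: int = 2,
    lattice_constant: float = 0.564,
    charge: float = 1.0,
) -> tuple[SystemTopology, Frame]:
    """A rock-salt +q/-q lattice (8 ions per cubic unit cell), periodic.

    The exact Coulomb energy per ion pair is -M k_e q^2 / d with Madelung
    constant M = 1.747565 and nearest-neighbour distance
    d = lattice_constant / 2.
    """
    if n_cells < 1:
        raise ValueError("need at least one unit cell")
    cation = MoleculeTopology(
        "cation", [AtomSpec("NA", "Na", mass=22.99, charge=+charge)]
    )
    anion = MoleculeTopology(
        "anion", [AtomSpec("CL", "Cl", mass=35.45, charge=-charge)]
    )
    half = lattice_constant / 2.0
    pos, sign = [], []
    for i in range(2 * n_cells):
        for j in range(2 * n_cells):
            for k in range(2 * n_cells):
                pos.append([i * half, j * half, k * half])
                sign.append(1 if (i + j + k) % 2 == 0 else -1)
    pos = np.asarray(pos)
    sign = np.asarray(sign)
    order = np.argsort(-sign, kind="stable")  # cations first, matching topology
    n_each = len(pos) // 2
    top = SystemTopology(
        [(cation, n_each), (anion, n_each)],
        roles={"cation": "api", "anion": "polymer"},
    )
    box = np.full(3, n_cells * lattice_constant)
    return top, Frame(pos[order], box=box, wrapped=True)


def gen_lj_lattice(
    n_side: int = 4,
    spacing: float = 0.4,
    sigma: float = 0.34,
    epsilon: float = 1.0,
) -> tuple[SystemTopology, Frame]:
    """A cubic lattice of identical LJ atoms in a periodic box."""
    atom = MoleculeTopology(
        "lj", [AtomSpec("AR", "Ar", mass=39.95, lj_sigma=sigma, lj_epsilon=epsilon)]
    )
    n = n_side**3
    top = SystemTopology([(atom, n)], roles={"lj": "api"})
    grid = np.stack(
        np.meshgrid(*[np.arange(n_side)] * 3, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    coords = grid * spacing
    box = np.full(3, n_side * spacing)
    return top, Frame(coords, box=box, wrapped=True)


def _toy_api() -> MoleculeTopology:
    return MoleculeTopology(
        "api",
        [
            AtomSpec("C1", "C", mass=12.011, charge=0.1, lj_sigma=0.34, lj_epsilon=0.36),
            AtomSpec("O1", "O", mass=15.999, charge=-0.5, lj_sigma=0.30, lj_epsilon=0.88,
                     is_acceptor=True),
            AtomSpec("H1", "H", mass=1.008, charge=0.4, is_donor_h=True),
        ],
        bonds=[Bond(0, 1, r0=0.14, k=2.0e5), Bond(1, 2, r0=_OH_BOND, k=3.0e5)],
    )


def _toy_polymer(monomers: int, charge_pattern: str) -> MoleculeTopology:
    """Acceptor-only comb: C(+q) backbone with pendant O(-q) acceptors,
    no donor hydrogens anywhere."""
    q = 0.3 if charge_pattern == "hbond" else 0.0
    atoms = []
    bonds = []
    for m in range(monomers):
        atoms.append(
            AtomSpec(f"C{m + 1}", "C", mass=12.011, charge=+q, lj_sigma=0.34,
                     lj_epsilon=0.36)
        )
        atoms.append(
            AtomSpec(f"O{m + 1}", "O", mass=15.999, charge=-q, lj_sigma=0.30,
                     lj_epsilon=0.88, is_acceptor=True)
        )
        base = 2 * m
        bonds.append(Bond(base, base + 1, r0=0.14, k=2.0e5))
        if m:
            bonds.append(Bond(base - 2, base, r0=0.28, k=2.0e5))
    return MoleculeTopology("polymer", atoms, bonds=bonds)


def gen_toy_blend(
    n_api: int = 8,
    n_chains: int = 2,
    monomers_per_chain: int = 6,
    charge_pattern: str = "hbond",
    n_frames: int = 5,
    n_replicates: int = 4,
    box: float | None = None,
    jitter: float = 0.01,
    seed: int = 0,
) -> tuple[SystemTopology, list[Trajectory]]:
    """A packed periodic drug-polymer toy with replicate trajectories.

    The "API" is a three-atom donor-bearing molecule; the "polymer" an
    acceptor-only chain (no donor hydrogens, so pure polymer cannot hydrogen
    bond — the configuration that rewards mixing with a donor-rich drug).
    API molecules are packed so their donor hydrogens point at polymer
    acceptor oxygens at H-bonding geometry. ``charge_pattern`` is ``hbond``
    (donor/acceptor partial charges) or ``zero`` (all charges off). Each of
    the ``n_replicates`` trajectories jitters the packed configuration with
    a different seed, mirroring the four independent repeats of a
    production study.
    """
    if charge_pattern not in ("hbond", "zero"):
        raise ValueError("charge_pattern must be 'hbond' or 'zero'")
    if n_api < 0 or n_chains < 0 or (n_api == 0 and n_chains == 0):
        raise ValueError("need at least one molecule")
    api = _toy_api()
    if charge_pattern == "zero":
        api = MoleculeTopology(
            "api",
            [AtomSpec(a.name, a.element, a.mass, 0.0, a.lj_sigma, a.lj_epsilon,
                      a.is_donor_h, a.is_acceptor) for a in api.atoms],
            bonds=api.bonds,
        )
    polymer = _toy_polymer(monomers_per_chain, charge_pattern)
    species: list[tuple[MoleculeTopology, int]] = []
    if n_api:
        species.append((api, n_api))
    if n_chains:
        species.append((polymer, n_chains))
    top = SystemTopology(species, roles={"api": "api", "polymer": "polymer"})
    if top.n_atoms > 500:
        raise ValueError("toy blend limited to 500 atoms")

    # packed configuration: straight comb backbones on shelves (C below its
    # pendant acceptor O), API molecules docked H-down onto the oxygens at
    # H-bonding geometry (D-A 0.296 nm, angle 0)
    chain_len = 0.28 * monomers_per_chain + 1.0
    n_shelves = max(n_chains, math.ceil(n_api / max(monomers_per_chain, 1)), 1)
    min_edge = max(chain_len, 2.0, 1.2 * n_shelves)
    edge = box if box is not None else min_edge
    if edge < min_edge - 1e-9:
        raise ValueError(
            f"box edge {edge} nm too small for {n_api} API + {n_chains} chains "
            f"(needs >= {min_edge:.2f} nm)"
        )
    coords = np.zeros((top.n_atoms, 3))
    api_slots: list[np.ndarray] = []  # acceptor-O positions APIs dock onto
    cursor = 3 * n_api  # API block is filled after the chains are placed
    for c in range(n_chains):
        y = (c + 0.5) * edge / max(n_chains, 1)
        for m in range(monomers_per_chain):
            cx = 0.5 + 0.28 * m
            coords[cursor] = [cx, y, 0.36]  # backbone C, displaced below
            coords[cursor + 1] = [cx, y, 0.50]  # pendant O acceptor
            api_slots.append(coords[cursor + 1].copy())
            cursor += 2
    rng_master = np.random.default_rng(seed)
    if n_api:
        if n_chains:
            slots = api_slots
        else:
            slots = list(_grid_points(n_api, edge))
        for a in range(n_api):
            base = 3 * a
            if n_chains:
                # dock above a chain oxygen; stacked layers sit too far to bond
                target = slots[a % len(slots)]
                level = a // len(slots)
                h_pos = target + np.array([0.0, 0.0, 0.20 + 0.6 * level])
            else:
                target = slots[a]
                h_pos = target + np.array([0.0, 0.0, 0.29])
            o_pos = h_pos + np.array([0.0, 0.0, _OH_BOND])
            c_pos = o_pos + np.array([0.0, 0.0, 0.14])
            coords[base + 0] = c_pos
            coords[base + 1] = o_pos
            coords[base + 2] = h_pos
    coords = np.mod(coords, edge)  # keep everything inside the box
    trajectories: list[Trajectory] = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(rng_master.integers(0, 2**31 - 1))
        frames = []
        for t in range(n_frames):
            noise = rng.normal(0.0, jitter, size=coords.shape) if jitter > 0 else 0.0
            frames.append(
                Frame(coords + noise, box=np.full(3, edge), time=2.0 * t, wrapped=False)
            )
        trajectories.append(Trajectory(frames))
    return top, trajectories
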