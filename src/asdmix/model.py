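"""Shared data model: atoms, molecular topologies, systems, frames, trajectories.

All quantities are stored in internal units (nm, ps, amu, e, kJ/mol).
Coordinates may be stored wrapped into the periodic box or unwrapped; the
``wrapped`` flag on :class:`Frame`/:class:`Trajectory` records which, since
mean-squared-displacement analysis is only valid on unwrapped coordinates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np


@dataclass(frozen=True)
class AtomSpec:
    """One atom of a molecular species.

    ``is_donor_h`` marks a hydrogen covalently bound to N or O (a hydrogen
    available for donation); ``is_acceptor`` marks an N or O lone-pair
    acceptor. Lennard-Jones parameters follow the sigma/epsilon convention.
    """

    name: str
    element: str
    mass: float
    charge: float = 0.0
    lj_sigma: float = 0.0
    lj_epsilon: float = 0.0
    is_donor_h: bool = False
    is_acceptor: bool = False

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.name!r}: mass must be > 0, got {self.mass}")
        if self.lj_sigma < 0 or self.lj_epsilon < 0:
            raise ValueError(f"atom {self.name!r}: LJ parameters must be >= 0")


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    r0: float = 0.1
    k: float = 0.0


@dataclass(frozen=True)
class Angle:
    i: int
    j: int  # vertex
    k: int
    theta0: float = 0.0  # rad
    k_theta: float = 0.0


@dataclass(frozen=True)
class Dihedral:
    i: int
    j: int
    k: int
    l: int
    periodicity: int = 1
    phase: float = 0.0  # rad
    k_phi: float = 0.0


class MoleculeTopology:
    """A molecular species: atoms plus bonded terms.

    Exclusion sets (atom pairs separated by 1, 2 or 3 bonds along the
    shortest bonded path) are derived from the bond graph on construction.
    """

    def __init__(
        self,
        name: str,
        atoms: Sequence[AtomSpec],
        bonds: Sequence[Bond] = (),
        angles: Sequence[Angle] = (),
        dihedrals: Sequence[Dihedral] = (),
    ) -> None:
        self.name = name
        self.atoms = tuple(atoms)
        self.bonds = tuple(bonds)
        self.angles = tuple(angles)
        self.dihedrals = tuple(dihedrals)
        n = len(self.atoms)
        for b in self.bonds:
            self._check_index("bond", (b.i, b.j), n)
        for a in self.angles:
            self._check_index("angle", (a.i, a.j, a.k), n)
        for d in self.dihedrals:
            self._check_index("dihedral", (d.i, d.j, d.k, d.l), n)
        self._pairs_by_separation = self._derive_exclusions()

    @staticmethod
    def _check_index(kind: str, idx: tuple[int, ...], n: int) -> None:
        for i in idx:
            if not (0 <= i < n):
                raise IndexError(f"{kind} index {i} out of range for {n} atoms")
        if len(set(idx)) != len(idx):
            raise ValueError(f"{kind} with repeated atom indices {idx}")

    def _derive_exclusions(self) -> dict[int, set[tuple[int, int]]]:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from((b.i, b.j) for b in self.bonds)
        pairs: dict[int, set[tuple[int, int]]] = {2: set(), 3: set(), 4: set()}
        for src in g.nodes:
            lengths = nx.single_source_shortest_path_length(g, src, cutoff=3)
            for dst, dist in lengths.items():
                if dst > src and dist >= 1:
                    pairs[dist + 1].add((src, dst))
        return pairs

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def pairs_separated_by(self, cls: int) -> frozenset[tuple[int, int]]:
        """Atom pairs in exclusion class ``cls`` (2 for 1-2, 3 for 1-3, 4 for 1-4)."""
        return frozenset(self._pairs_by_separation[cls])

    @property
    def exclusion_sets(self) -> tuple[frozenset[int], ...]:
        """Per-atom sets of atoms within three bonds (symmetric)."""
        sets: list[set[int]] = [set() for _ in self.atoms]
        for cls in (2, 3, 4):
            for i, j in self._pairs_by_separation[cls]:
                sets[i].add(j)
                sets[j].add(i)
        return tuple(frozenset(s) for s in sets)

    @property
    def mass(self) -> float:
        return float(sum(a.mass for a in self.atoms))

    @property
    def net_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))


@dataclass(frozen=True)
class MoleculeInstance:
    """One copy of a species inside a system's flat atom table."""

    species: str
    role: str
    index: int  # global molecule-instance index
    atom_start: int
    n_atoms: int

    @property
    def atom_indices(self) -> np.ndarray:
        return np.arange(self.atom_start, self.atom_start + self.n_atoms)


class SystemTopology:
    """A simulated system: species with counts and api/polymer roles.

    Provides the flattened per-atom arrays (charges, LJ parameters, masses,
    molecule membership) and global exclusion pair lists the energy and
    analysis code consumes.
    """

    def __init__(
        self,
        molecules: Sequence[tuple[MoleculeTopology, int]],
        roles: dict[str, str] | None = None,
    ) -> None:
        roles = dict(roles or {})
        self.molecules = tuple((m, int(c)) for m, c in molecules)
        for mol, count in self.molecules:
            if count < 0:
                raise ValueError(f"negative count {count} for species {mol.name!r}")
        self.roles = {
            mol.name: roles.get(mol.name, "api") for mol, _ in self.molecules
        }
        for name, role in self.roles.items():
            if role not in ("api", "polymer"):
                raise ValueError(f"role for {name!r} must be 'api' or 'polymer'")
        self._build_flat_tables()

    def _build_flat_tables(self) -> None:
        instances: list[MoleculeInstance] = []
        charges: list[float] = []
        sigmas: list[float] = []
        epsilons: list[float] = []
        masses: list[float] = []
        elements: list[str] = []
        donor_h: list[bool] = []
        acceptor: list[bool] = []
        atom_mol: list[int] = []
        offset = 0
        for mol, count in self.molecules:
            role = self.roles[mol.name]
            for _ in range(count):
                instances.append(
                    MoleculeInstance(mol.name, role, len(instances), offset, mol.n_atoms)
                )
                for a in mol.atoms:
                    charges.append(a.charge)
                    sigmas.append(a.lj_sigma)
                    epsilons.append(a.lj_epsilon)
                    masses.append(a.mass)
                    elements.append(a.element)
                    donor_h.append(a.is_donor_h)
                    acceptor.append(a.is_acceptor)
                    atom_mol.append(len(instances) - 1)
                offset += mol.n_atoms
        self.instances: tuple[MoleculeInstance, ...] = tuple(instances)
        self.charges = np.asarray(charges, dtype=float)
        self.lj_sigma = np.asarray(sigmas, dtype=float)
        self.lj_epsilon = np.asarray(epsilons, dtype=float)
        self.masses = np.asarray(masses, dtype=float)
        self.elements = tuple(elements)
        self.is_donor_h = np.asarray(donor_h, dtype=bool)
        self.is_acceptor = np.asarray(acceptor, dtype=bool)
        self.atom_molecule = np.asarray(atom_mol, dtype=int)
        self.n_atoms = offset
        self._excl_pairs: np.ndarray | None = None
        self._pairs_14: np.ndarray | None = None

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(mol.name for mol, _ in self.molecules)

    def species_topology(self, name: str) -> MoleculeTopology:
        for mol, _ in self.molecules:
            if mol.name == name:
                return mol
        raise KeyError(f"unknown species {name!r}")

    def species_count(self, name: str) -> int:
        for mol, count in self.molecules:
            if mol.name == name:
                return count
        raise KeyError(f"unknown species {name!r}")

    def instances_of(self, species: str) -> tuple[MoleculeInstance, ...]:
        if species not in self.species:
            raise KeyError(f"unknown species {species!r}")
        return tuple(inst for inst in self.instances if inst.species == species)

    def _global_pairs(self, cls_list: tuple[int, ...]) -> np.ndarray:
        pairs: list[tuple[int, int]] = []
        offset = 0
        for mol, count in self.molecules:
            local = sorted(
                itertools.chain.from_iterable(
                    mol.pairs_separated_by(c) for c in cls_list
                )
            )
            for _ in range(count):
                pairs.extend((offset + i, offset + j) for i, j in local)
                offset += mol.n_atoms
        if not pairs:
            return np.empty((0, 2), dtype=int)
        return np.asarray(pairs, dtype=int)

    @property
    def excluded_pairs(self) -> np.ndarray:
        """Global (i, j) pairs excluded from non-bonded sums (1-2, 1-3, 1-4)."""
        if self._excl_pairs is None:
            self._excl_pairs = self._global_pairs((2, 3, 4))
        return self._excl_pairs

    @property
    def pairs_14(self) -> np.ndarray:
        """Global (i, j) 1-4 pairs (scaled non-bonded in total energies)."""
        if self._pairs_14 is None:
            self._pairs_14 = self._global_pairs((4,))
        return self._pairs_14

    def exclusion_mask(self) -> np.ndarray:
        """Boolean (N, N) matrix: True where the pair is excluded (incl. self)."""
        mask = np.zeros((self.n_atoms, self.n_atoms), dtype=bool)
        np.fill_diagonal(mask, True)
        ep = self.excluded_pairs
        if len(ep):
            mask[ep[:, 0], ep[:, 1]] = True
            mask[ep[:, 1], ep[:, 0]] = True
        return mask

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())


@dataclass
class Frame:
    """One trajectory frame: coordinates (nm) plus an orthorhombic box."""

    coordinates: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0  # ps
    wrapped: bool = False

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(self.box <= 0):
                raise ValueError(f"box edges must be > 0, got {self.box}")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def validate_against(self, topology: SystemTopology) -> None:
        if self.n_atoms != topology.n_atoms:
            raise ValueError(
                f"frame has {self.n_atoms} atoms, topology {topology.n_atoms}"
            )


class Trajectory:
    """Time-ordered frames with constant spacing ``dt`` (ps)."""

    #: relative tolerance on dt constancy
    DT_RTOL = 1e-6

    def __init__(self, frames: Iterable[Frame]) -> None:
        self.frames: list[Frame] = list(frames)
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        n0 = self.frames[0].n_atoms
        for idx, f in enumerate(self.frames):
            if f.n_atoms != n0:
                raise ValueError(
                    f"frame {idx} has {f.n_atoms} atoms, expected {n0}"
                )
        times = self.times
        if len(times) > 1:
            steps = np.diff(times)
            if np.any(steps <= 0):
                raise ValueError("frame times must be strictly increasing")
            dt = steps[0]
            if np.any(np.abs(steps - dt) > self.DT_RTOL * max(abs(dt), 1.0)):
                raise ValueError("frame spacing dt must be constant")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, idx: int) -> Frame:
        return self.frames[idx]

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    @property
    def times(self) -> np.ndarray:
        return np.asarray([f.time for f in self.frames], dtype=float)

    @property
    def dt(self) -> float:
        if len(self.frames) < 2:
            raise ValueError("dt undefined for a single-frame trajectory")
        return float(self.frames[1].time - self.frames[0].time)

    @property
    def wrapped(self) -> bool:
        return any(f.wrapped for f in self.frames)

    @property
    def coords(self) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, n_atoms, 3)."""
        return np.stack([f.coordinates for f in self.frames])

    @property
    def boxes(self) -> np.ndarray | None:
        if self.frames[0].box is None:
            return None
        return np.stack([f.box for f in self.frames])
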