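"""Structure, trajectory and topology file I/O.

Supported structure formats: GRO (fixed-column, coordinates in nm), a PDB
subset (ATOM/HETATM/CRYST1, Angstrom), and XYZ (Angstrom). Trajectories are
multi-frame GRO or XYZ files. Topologies are a documented YAML format (see
:func:`load_topology`). All coordinates are converted to nm on read.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

from .constants import ATOMIC_WEIGHTS, NM_PER_ANGSTROM
from .model import (
    Angle,
    AtomSpec,
    Bond,
    Dihedral,
    Frame,
    MoleculeTopology,
    SystemTopology,
    Trajectory,
)


class ParseError(ValueError):
    """Raised for malformed input files; carries the offending line number."""

    def __init__(self, path: str | Path, line_no: int, message: str) -> None:
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


_TIME_RE = re.compile(r"t\s*=\s*([-+0-9.eE]+)")


def _guess_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("gro", "pdb", "xyz"):
        return suffix
    raise ValueError(f"cannot infer format from {path!r}; pass format=")


def _skeleton_topology(
    names: list[str], elements: list[str], resids: list[int], resnames: list[str]
) -> SystemTopology:
    """Group contiguous residue runs into single-count molecule instances."""
    molecules: list[tuple[MoleculeTopology, int]] = []
    start = 0
    n = len(names)
    for i in range(1, n + 1):
        if i == n or resids[i] != resids[start] or resnames[i] != resnames[start]:
            atoms = [
                AtomSpec(
                    name=names[k],
                    element=elements[k],
                    mass=ATOMIC_WEIGHTS.get(elements[k], 1.0),
                )
                for k in range(start, i)
            ]
            molecules.append(
                (MoleculeTopology(f"{resnames[start]}_{len(molecules)}", atoms), 1)
            )
            start = i
    return SystemTopology(molecules)


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].capitalize() in ATOMIC_WEIGHTS:
        return stripped[:2].capitalize()
    if stripped and stripped[0].upper() in ATOMIC_WEIGHTS:
        return stripped[0].upper()
    return stripped[:1].upper() or "X"


# ---------------------------------------------------------------------------
# GRO


def _parse_gro_block(lines: list[str], path: str | Path, line0: int):
    title = lines[0]
    try:
        n_atoms = int(lines[1].strip())
    except ValueError:
        raise ParseError(path, line0 + 2, f"expected atom count, got {lines[1]!r}")
    if len(lines) < n_atoms + 3:
        raise ParseError(
            path, line0 + len(lines), f"truncated GRO block: need {n_atoms} atom lines"
        )
    names, elements, resids, resnames = [], [], [], []
    coords = np.empty((n_atoms, 3))
    for k in range(n_atoms):
        line = lines[2 + k]
        ln = line0 + 3 + k
        if len(line.rstrip("\n")) < 44:
            raise ParseError(path, ln, f"GRO atom line too short: {line!r}")
        try:
            resids.append(int(line[0:5]))
            resnames.append(line[5:10].strip())
            names.append(line[10:15].strip())
            coords[k] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
        except ValueError as exc:
            raise ParseError(path, ln, f"malformed GRO atom line: {exc}")
        elements.append(_element_from_name(names[-1]))
    box_line = lines[2 + n_atoms].split()
    try:
        box_vals = [float(v) for v in box_line[:3]]
    except (ValueError, IndexError):
        raise ParseError(path, line0 + 3 + n_atoms, "malformed GRO box line")
    box = np.asarray(box_vals) if any(v > 0 for v in box_vals) else None
    m = _TIME_RE.search(title)
    time = float(m.group(1)) if m else 0.0
    frame = Frame(coords, box=box, time=time)
    return frame, names, elements, resids, resnames


def _iter_gro_frames(path: str | Path):
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise ParseError(path, 1, "empty file")
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip() and pos == len(lines) - 1:
            break
        try:
            n_atoms = int(lines[pos + 1].strip())
        except (IndexError, ValueError):
            raise ParseError(path, pos + 2, "expected atom count line")
        block = lines[pos : pos + n_atoms + 3]
        yield _parse_gro_block(block, path, pos)
        pos += n_atoms + 3


def _write_gro_frame(fh, frame: Frame, topology: SystemTopology | None) -> None:
    fh.write(f"frame t= {frame.time:.6f}\n{frame.n_atoms:5d}\n")
    if topology is not None:
        names = [a.name for mol, c in topology.molecules for _ in range(c) for a in mol.atoms]
        resids = (topology.atom_molecule % 99999) + 1
        resnames = [topology.instances[m].species[:5] for m in topology.atom_molecule]
    else:
        names = [f"X{i + 1}" for i in range(frame.n_atoms)]
        resids = np.ones(frame.n_atoms, dtype=int)
        resnames = ["MOL"] * frame.n_atoms
    for i, (x, y, z) in enumerate(frame.coordinates):
        fh.write(
            f"{resids[i]:5d}{resnames[i]:<5s}{names[i][:5]:>5s}{(i % 99999) + 1:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
        )
    box = frame.box if frame.box is not None else np.zeros(3)
    fh.write(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# XYZ


def _iter_xyz_frames(path: str | Path):
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise ParseError(path, 1, "empty file")
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].strip())
        except ValueError:
            raise ParseError(path, pos + 1, f"expected atom count, got {lines[pos]!r}")
        if pos + 2 + n_atoms > len(lines):
            raise ParseError(path, len(lines), "truncated XYZ frame")
        comment = lines[pos + 1]
        names, elements = [], []
        coords = np.empty((n_atoms, 3))
        for k in range(n_atoms):
            parts = lines[pos + 2 + k].split()
            ln = pos + 3 + k
            if len(parts) < 4:
                raise ParseError(path, ln, f"malformed XYZ atom line: {lines[pos + 2 + k]!r}")
            try:
                coords[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise ParseError(path, ln, f"malformed XYZ coordinates: {exc}")
            names.append(parts[0])
            elements.append(_element_from_name(parts[0]))
        coords *= NM_PER_ANGSTROM
        m = _TIME_RE.search(comment)
        time = float(m.group(1)) if m else 0.0
        bm = re.search(r"box\s*=\s*([-+0-9.eE]+)\s+([-+0-9.eE]+)\s+([-+0-9.eE]+)", comment)
        box = (
            np.asarray([float(bm.group(i)) for i in (1, 2, 3)]) * NM_PER_ANGSTROM
            if bm
            else None
        )
        yield (
            Frame(coords, box=box, time=time),
            names,
            elements,
            list(range(n_atoms)),
            ["MOL"] * n_atoms,
        )
        pos += 2 + n_atoms


def _write_xyz_frame(fh, frame: Frame, topology: SystemTopology | None) -> None:
    elements = (
        list(topology.elements) if topology is not None else ["X"] * frame.n_atoms
    )
    comment = f"t= {frame.time:.6f}"
    if frame.box is not None:
        bx = frame.box * 10.0
        comment += f" box= {bx[0]:.6f} {bx[1]:.6f} {bx[2]:.6f}"
    fh.write(f"{frame.n_atoms}\n{comment}\n")
    for el, (x, y, z) in zip(elements, frame.coordinates * 10.0):
        fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# PDB subset


def _iter_pdb_frames(path: str | Path):
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise ParseError(path, 1, "empty file")
    box = None
    names, elements, resids, resnames = [], [], [], []
    coords: list[list[float]] = []
    n_frame = 0

    def flush():
        nonlocal names, elements, resids, resnames, coords, n_frame
        if not coords:
            return None
        frame = Frame(
            np.asarray(coords) * NM_PER_ANGSTROM, box=box, time=float(n_frame)
        )
        out = (frame, names, elements, resids, resnames)
        names, elements, resids, resnames, coords = [], [], [], [], []
        n_frame += 1
        return out

    for ln, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec == "CRYST1":
            try:
                box = (
                    np.asarray([float(line[6:15]), float(line[15:24]), float(line[24:33])])
                    * NM_PER_ANGSTROM
                )
            except ValueError as exc:
                raise ParseError(path, ln, f"malformed CRYST1 record: {exc}")
        elif rec in ("ATOM", "HETATM"):
            try:
                names.append(line[12:16].strip())
                resnames.append(line[17:20].strip() or "MOL")
                resids.append(int(line[22:26]) if line[22:26].strip() else 1)
                coords.append(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
            except ValueError as exc:
                raise ParseError(path, ln, f"malformed {rec} record: {exc}")
            el = line[76:78].strip() if len(line) >= 78 else ""
            elements.append(el.capitalize() if el else _element_from_name(names[-1]))
        elif rec == "ENDMDL":
            out = flush()
            if out is not None:
                yield out
    out = flush()
    if out is not None:
        yield out
    elif n_frame == 0:
        raise ParseError(path, len(lines), "no ATOM/HETATM records found")


def _write_pdb_frame(fh, frame: Frame, topology: SystemTopology | None) -> None:
    if frame.box is not None:
        b = frame.box * 10.0
        fh.write(
            f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}  90.00  90.00  90.00 P 1           1\n"
        )
    if topology is not None:
        names = [a.name for mol, c in topology.molecules for _ in range(c) for a in mol.atoms]
        elements = list(topology.elements)
        resids = (topology.atom_molecule % 9999) + 1
        resnames = [topology.instances[m].species[:3].upper() for m in topology.atom_molecule]
    else:
        names = [f"X{i + 1}" for i in range(frame.n_atoms)]
        elements = ["X"] * frame.n_atoms
        resids = np.ones(frame.n_atoms, dtype=int)
        resnames = ["MOL"] * frame.n_atoms
    for i, (x, y, z) in enumerate(frame.coordinates * 10.0):
        fh.write(
            f"HETATM{(i % 99999) + 1:5d} {names[i][:4]:<4s} {resnames[i]:<3s}  "
            f"{resids[i]:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            f"          {elements[i][:2]:>2s}\n"
        )
    fh.write("END\n")


# ---------------------------------------------------------------------------
# Public API

_ITERATORS = {"gro": _iter_gro_frames, "xyz": _iter_xyz_frames, "pdb": _iter_pdb_frames}
_WRITERS = {"gro": _write_gro_frame, "xyz": _write_xyz_frame, "pdb": _write_pdb_frame}


def read_structure(
    path: str | Path, format: str | None = None
) -> tuple[SystemTopology, Frame]:
    """Read the first frame of a structure file.

    Returns a skeleton :class:`SystemTopology` (atom names/elements grouped
    by residue, no bonded terms or charges) and the :class:`Frame`. GRO
    coordinates are interpreted in nm, PDB and XYZ in Angstrom.
    """
    fmt = _guess_format(path, format)
    frame, names, elements, resids, resnames = next(_ITERATORS[fmt](path))
    return _skeleton_topology(names, elements, resids, resnames), frame


def write_structure(
    path: str | Path,
    frame: Frame,
    topology: SystemTopology | None = None,
    format: str | None = None,
) -> None:
    fmt = _guess_format(path, format)
    if topology is not None:
        frame.validate_against(topology)
    with open(path, "w") as fh:
        _WRITERS[fmt](fh, frame, topology)


def iter_frames(path: str | Path, format: str | None = None) -> Iterator[Frame]:
    """Stream frames of a multi-frame GRO/XYZ/PDB file one at a time."""
    fmt = _guess_format(path, format)
    for frame, *_ in _ITERATORS[fmt](path):
        yield frame


def read_trajectory(
    path: str | Path, format: str | None = None, wrapped: bool = False
) -> Trajectory:
    """Read a multi-frame trajectory file into memory.

    ``wrapped`` stamps every frame with the wrapped/unwrapped flag, since
    the file formats do not record it.
    """
    frames = []
    n_atoms = None
    for idx, frame in enumerate(iter_frames(path, format)):
        if n_atoms is None:
            n_atoms = frame.n_atoms
        elif frame.n_atoms != n_atoms:
            raise ValueError(
                f"{path}: frame {idx} has {frame.n_atoms} atoms, expected {n_atoms}"
            )
        frame.wrapped = wrapped
        frames.append(frame)
    times = [f.time for f in frames]
    if len(frames) > 1 and any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        # format carried no usable time metadata; fall back to frame indices
        for idx, frame in enumerate(frames):
            frame.time = float(idx)
    return Trajectory(frames)


def write_trajectory(
    path: str | Path,
    traj: Trajectory,
    topology: SystemTopology | None = None,
    format: str | None = None,
) -> None:
    fmt = _guess_format(path, format)
    with open(path, "w") as fh:
        for frame in traj:
            _WRITERS[fmt](fh, frame, topology)


# ---------------------------------------------------------------------------
# Topology config


def _atom_from_config(entry: dict) -> AtomSpec:
    return AtomSpec(
        name=str(entry["name"]),
        element=str(entry["element"]),
        mass=float(entry.get("mass", ATOMIC_WEIGHTS.get(str(entry["element"]), 1.0))),
        charge=float(entry.get("charge", 0.0)),
        lj_sigma=float(entry.get("sigma", 0.0)),
        lj_epsilon=float(entry.get("epsilon", 0.0)),
        is_donor_h=bool(entry.get("donor_h", False)),
        is_acceptor=bool(entry.get("acceptor", False)),
    )


def molecule_from_config(entry: dict) -> MoleculeTopology:
    atoms = [_atom_from_config(a) for a in entry.get("atoms", [])]
    bonds = [Bond(int(b[0]), int(b[1]), *map(float, b[2:4])) for b in entry.get("bonds", [])]
    angles = [
        Angle(int(a[0]), int(a[1]), int(a[2]), *map(float, a[3:5]))
        for a in entry.get("angles", [])
    ]
    dihedrals = [
        Dihedral(int(d[0]), int(d[1]), int(d[2]), int(d[3]), int(d[4]), float(d[5]), float(d[6]))
        for d in entry.get("dihedrals", [])
    ]
    return MoleculeTopology(str(entry["name"]), atoms, bonds, angles, dihedrals)


def load_topology(path: str | Path) -> SystemTopology:
    """Load a system topology from the package's YAML config format.

    Schema::

        molecules:
          - name: api
            role: api            # api | polymer
            count: 95
            atoms:
              - {name: O1, element: O, mass: 15.999, charge: -0.5,
                 sigma: 0.30, epsilon: 0.7, acceptor: true}
            bonds:     [[i, j, r0_nm, k_kJ_mol_nm2], ...]
            angles:    [[i, j, k, theta0_rad, k_kJ_mol_rad2], ...]
            dihedrals: [[i, j, k, l, periodicity, phase_rad, k_kJ_mol], ...]

    Exclusion sets (1-2, 1-3, 1-4) are derived from the bond graph.
    """
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict) or "molecules" not in config:
        raise ValueError(f"{path}: topology config must contain a 'molecules' list")
    molecules: list[tuple[MoleculeTopology, int]] = []
    roles: dict[str, str] = {}
    for entry in config["molecules"]:
        mol = molecule_from_config(entry)
        count = int(entry.get("count", 1))
        if count < 0:
            raise ValueError(f"{path}: negative count for species {mol.name!r}")
        molecules.append((mol, count))
        roles[mol.name] = str(entry.get("role", "api"))
    return SystemTopology(molecules, roles)
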