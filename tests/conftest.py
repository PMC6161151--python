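"""Shared fixtures: small hand-built systems and random toy blends."""

from __future__ import annotations

import numpy as np
import pytest

from asdmix.model import (
    AtomSpec,
    Bond,
    Frame,
    MoleculeTopology,
    SystemTopology,
)


def make_chain_molecule(
    name: str,
    n_atoms: int,
    charges: list[float] | None = None,
    sigma: float = 0.3,
    epsilon: float = 0.5,
    element: str = "C",
) -> MoleculeTopology:
    """A linear chain A-B-C-... with optional charges and uniform LJ."""
    atoms = [
        AtomSpec(
            f"{element}{i + 1}",
            element,
            mass=12.0,
            charge=0.0 if charges is None else charges[i],
            lj_sigma=sigma,
            lj_epsilon=epsilon,
        )
        for i in range(n_atoms)
    ]
    bonds = [Bond(i, i + 1, r0=0.15, k=1.0e5) for i in range(n_atoms - 1)]
    return MoleculeTopology(name, atoms, bonds=bonds)


def make_random_blend(
    seed: int,
    n_api: int = 6,
    n_pol: int = 4,
    atoms_per_api: int = 4,
    atoms_per_pol: int = 8,
    box: float = 4.0,
) -> tuple[SystemTopology, Frame]:
    """Random two-species charged toy in a periodic box.

    Charges are random but neutral per molecule; molecules are placed at
    random centres with compact random internal geometry, so atoms never
    coincide and both species interact across molecules.
    """
    rng = np.random.default_rng(seed)

    def charges(n: int) -> list[float]:
        q = rng.uniform(-0.5, 0.5, size=n)
        return list(q - q.mean())

    api = make_chain_molecule("api", atoms_per_api, charges(atoms_per_api))
    pol = make_chain_molecule("pol", atoms_per_pol, charges(atoms_per_pol))
    top = SystemTopology(
        [(api, n_api), (pol, n_pol)], roles={"api": "api", "pol": "polymer"}
    )
    coords = np.empty((top.n_atoms, 3))
    cursor = 0
    for inst in top.instances:
        centre = rng.uniform(0.5, box - 0.5, size=3)
        local = rng.normal(0.0, 0.12, size=(inst.n_atoms, 3))
        coords[cursor : cursor + inst.n_atoms] = centre + local
        cursor += inst.n_atoms
    return top, Frame(coords, box=np.full(3, box), wrapped=False)


@pytest.fixture
def charged_pair():
    """+1/-1 point charges 1 nm apart, non-periodic."""
    plus = MoleculeTopology("plus", [AtomSpec("P", "Na", 22.99, charge=1.0)])
    minus = MoleculeTopology("minus", [AtomSpec("M", "Cl", 35.45, charge=-1.0)])
    top = SystemTopology([(plus, 1), (minus, 1)])
    frame = Frame(np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]))
    return top, frame
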