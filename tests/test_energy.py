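"""Energy engine: closed-form LJ/Coulomb/bonded values, brute-force oracles,
Ewald vs Evjen Madelung summation, and the charge-zeroing decomposition."""

from __future__ import annotations

import math

import numpy as np
import pytest

from asdmix.constants import COULOMB_CONSTANT as KE
from asdmix.constants import FUDGE_LJ, FUDGE_QQ
from asdmix.energy import (
    EwaldParams,
    bonded_energy,
    coulomb_energy,
    intermolecular_coulomb_by_zeroing,
    lj_energy,
    species_intermolecular_coulomb,
    total_energy,
)
from asdmix.model import (
    Angle,
    AtomSpec,
    Bond,
    Dihedral,
    Frame,
    MoleculeTopology,
    SystemTopology,
)
from asdmix.synthetic import gen_lj_lattice, gen_rock_salt

from conftest import make_random_blend


def lj_pair_system(r, sigma=0.34, epsilon=1.2):
    atom = MoleculeTopology(
        "a", [AtomSpec("AR", "Ar", 39.95, lj_sigma=sigma, lj_epsilon=epsilon)]
    )
    top = SystemTopology([(atom, 2)])
    return top, Frame(np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]))


# ---------------------------------------------------------------------------
# Lennard-Jones


@pytest.mark.parametrize(
    "r_factor, expected_factor",
    [(1.0, 0.0), (2.0 ** (1.0 / 6.0), -1.0)],
    ids=["zero-crossing", "minimum"],
)
def test_lj_two_atom_closed_form(r_factor, expected_factor):
    sigma, epsilon = 0.34, 1.2
    top, frame = lj_pair_system(r_factor * sigma, sigma, epsilon)
    e = lj_energy(frame, top, cutoff=None)
    assert e == pytest.approx(expected_factor * epsilon, abs=1e-12)


def test_lj_lattice_matches_brute_force_image_sum():
    top, frame = gen_lj_lattice(n_side=4, spacing=0.4, sigma=0.34, epsilon=1.0)
    cutoff = 0.7
    e = lj_energy(frame, top, cutoff=cutoff)
    # naive all-image double loop truncated at the cutoff
    coords, box = frame.coordinates, frame.box
    shifts = np.array(
        [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    ) * box
    expected = 0.0
    n = top.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            d = coords[j] - coords[i]
            r = np.linalg.norm(d + shifts, axis=1)
            for rr in r[r <= cutoff]:
                sr6 = (0.34 / rr) ** 6
                expected += 4.0 * (sr6 * sr6 - sr6)
    assert e == pytest.approx(expected, rel=1e-10)


def test_lj_tail_correction_is_negative():
    top, frame = gen_lj_lattice(n_side=3, spacing=0.45)
    e_plain = lj_energy(frame, top, cutoff=0.6)
    e_tail = lj_energy(frame, top, cutoff=0.6, tail_correction=True)
    assert e_tail < e_plain


def test_lj_cutoff_exceeding_half_box_raises():
    top, frame = gen_lj_lattice(n_side=3, spacing=0.4)  # box edge 1.2 nm
    with pytest.raises(ValueError, match="cutoff"):
        lj_energy(frame, top, cutoff=0.7)


# ---------------------------------------------------------------------------
# Coulomb


@pytest.mark.parametrize("method", ["direct", "minimum-image", "ewald"])
def test_coulomb_zero_charges_is_zero(method):
    mol = MoleculeTopology("m", [AtomSpec("C1", "C", 12.0), AtomSpec("C2", "C", 12.0)])
    top = SystemTopology([(mol, 3)])
    rng = np.random.default_rng(0)
    frame = Frame(rng.uniform(0.3, 2.7, size=(6, 3)), box=np.full(3, 3.0))
    assert coulomb_energy(frame, top, method=method, cutoff=0.9) == 0.0


def test_coulomb_unit_charge_pair_direct(charged_pair):
    top, frame = charged_pair
    assert coulomb_energy(frame, top, method="direct") == pytest.approx(
        -138.935458, abs=1e-9
    )


def evjen_madelung(n_shells: int = 8) -> float:
    """NaCl Madelung constant by Evjen's neutralized-cube summation.

    Fractional weights (1/2 face, 1/4 edge, 1/8 corner) make each cube
    neutral, so the shell sum converges rapidly; independent of Ewald.
    """
    n = n_shells
    total = 0.0
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            for k in range(-n, n + 1):
                if i == j == k == 0:
                    continue
                w = 1.0
                for c in (i, j, k):
                    if abs(c) == n:
                        w *= 0.5
                total += w * (-1.0) ** (i + j + k) / math.sqrt(i * i + j * j + k * k)
    return -total


def test_ewald_rock_salt_matches_evjen_madelung():
    lattice = 0.564
    top, frame = gen_rock_salt(n_cells=2, lattice_constant=lattice)
    e = coulomb_energy(
        frame, top, method="ewald", ewald=EwaldParams(cutoff=0.55, accuracy=1e-6)
    )
    d = lattice / 2.0
    per_pair = e / (top.n_atoms // 2)
    reference = -evjen_madelung(8) * KE / d
    assert per_pair == pytest.approx(reference, rel=1e-4)


def test_ewald_invariant_under_lattice_translation():
    top, frame = gen_rock_salt(n_cells=2)
    params = EwaldParams(cutoff=0.55)
    e0 = coulomb_energy(frame, top, method="ewald", ewald=params)
    shifted = Frame(
        np.mod(frame.coordinates + np.array([0.173, -0.529, 0.311]), frame.box),
        box=frame.box,
    )
    e1 = coulomb_energy(shifted, top, method="ewald", ewald=params)
    assert e1 == pytest.approx(e0, rel=1e-8)


def test_ewald_converges_to_direct_for_isolated_dimer(charged_pair):
    top, _ = charged_pair
    frame = Frame(
        np.array([[10.0, 10.0, 10.0], [10.2, 10.0, 10.0]]), box=np.full(3, 20.0)
    )
    e_direct = coulomb_energy(frame, top, method="direct")
    e_ewald = coulomb_energy(
        frame, top, method="ewald", ewald=EwaldParams(cutoff=6.0, accuracy=1e-6)
    )
    assert e_ewald == pytest.approx(e_direct, rel=1e-4)


def test_ewald_non_neutral_system_warns():
    ion = MoleculeTopology("ion", [AtomSpec("NA", "Na", 22.99, charge=1.0)])
    top = SystemTopology([(ion, 2)])
    frame = Frame(np.array([[0.5, 0.5, 0.5], [1.5, 1.5, 1.5]]), box=np.full(3, 3.0))
    with pytest.warns(UserWarning, match="non-neutral"):
        coulomb_energy(frame, top, method="ewald", ewald=EwaldParams(cutoff=1.0))


def test_overlapping_charged_atoms_raise(charged_pair):
    top, _ = charged_pair
    frame = Frame(np.array([[0.0, 0.0, 0.0], [1e-8, 0.0, 0.0]]))
    with pytest.raises(ValueError, match="overlap"):
        coulomb_energy(frame, top, method="direct")


def test_direct_energies_invariant_under_rigid_rotation():
    top, frame = make_random_blend(seed=11, box=4.0)
    open_frame = Frame(frame.coordinates)  # drop periodicity
    theta = 0.7
    rot = np.array(
        [
            [math.cos(theta), -math.sin(theta), 0.0],
            [math.sin(theta), math.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    rotated = Frame(open_frame.coordinates @ rot.T)
    assert coulomb_energy(rotated, top, "direct") == pytest.approx(
        coulomb_energy(open_frame, top, "direct"), rel=1e-12
    )
    assert lj_energy(rotated, top, cutoff=None) == pytest.approx(
        lj_energy(open_frame, top, cutoff=None), rel=1e-12
    )


# ---------------------------------------------------------------------------
# bonded terms


def test_bond_energy_closed_form():
    mol = MoleculeTopology(
        "m",
        [AtomSpec("A", "C", 12.0), AtomSpec("B", "C", 12.0)],
        bonds=[Bond(0, 1, r0=0.15, k=1000.0)],
    )
    top = SystemTopology([(mol, 1)])
    at_rest = Frame(np.array([[0.0, 0.0, 0.0], [0.15, 0.0, 0.0]]))
    assert bonded_energy(at_rest, top)[0] == pytest.approx(0.0, abs=1e-12)
    displaced = Frame(np.array([[0.0, 0.0, 0.0], [0.15 + 0.02, 0.0, 0.0]]))
    assert bonded_energy(displaced, top)[0] == pytest.approx(
        0.5 * 1000.0 * 0.02**2, rel=1e-12
    )


def test_angle_energy_closed_form():
    mol = MoleculeTopology(
        "m",
        [AtomSpec(n, "C", 12.0) for n in "ABC"],
        bonds=[Bond(0, 1), Bond(1, 2)],
        angles=[Angle(0, 1, 2, theta0=math.pi / 2, k_theta=400.0)],
    )
    top = SystemTopology([(mol, 1)])
    frame = Frame(np.array([[0.1, 0.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.1, 0.0]]))
    assert bonded_energy(frame, top)[1] == pytest.approx(0.0, abs=1e-12)
    # 60-degree geometry: deviation pi/6
    frame2 = Frame(
        np.array(
            [[0.1, 0.0, 0.0], [0.0, 0.0, 0.0], [0.1 * math.cos(math.pi / 3), 0.1 * math.sin(math.pi / 3), 0.0]]
        )
    )
    assert bonded_energy(frame2, top)[1] == pytest.approx(
        0.5 * 400.0 * (math.pi / 6) ** 2, rel=1e-9
    )


def test_dihedral_at_phase_angle_gives_twice_barrier():
    # trans (phi = pi) butane-like chain with phase pi, n = 1: k (1 + cos 0) = 2k
    mol = MoleculeTopology(
        "m",
        [AtomSpec(n, "C", 12.0) for n in "ABCD"],
        bonds=[Bond(0, 1), Bond(1, 2), Bond(2, 3)],
        dihedrals=[Dihedral(0, 1, 2, 3, periodicity=1, phase=math.pi, k_phi=5.0)],
    )
    top = SystemTopology([(mol, 1)])
    frame = Frame(
        np.array([[0.0, 0.1, 0.0], [0.0, 0.0, 0.0], [0.15, 0.0, 0.0], [0.15, -0.1, 0.0]])
    )
    assert bonded_energy(frame, top)[2] == pytest.approx(2.0 * 5.0, rel=1e-12)


def test_zero_length_angle_vector_raises():
    mol = MoleculeTopology(
        "m",
        [AtomSpec(n, "C", 12.0) for n in "ABC"],
        bonds=[Bond(0, 1), Bond(1, 2)],
        angles=[Angle(0, 1, 2, theta0=1.0, k_theta=1.0)],
    )
    top = SystemTopology([(mol, 1)])
    frame = Frame(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0], [0.1, 0.0, 0.0]]))
    with pytest.raises(ValueError, match="zero-length"):
        bonded_energy(frame, top)


# ---------------------------------------------------------------------------
# assembled breakdown


def naive_total_energy(frame, top):
    """Independent full double-loop evaluation (direct Coulomb, no cutoff),
    re-deriving exclusions from each molecule's bond graph by path search."""
    coords = frame.coordinates
    q, sig, eps = top.charges, top.lj_sigma, top.lj_epsilon
    mol_of = top.atom_molecule
    separation = {}
    for inst in top.instances:
        mtop = top.species_topology(inst.species)
        for cls in (2, 3, 4):
            for i, j in mtop.pairs_separated_by(cls):
                separation[(inst.atom_start + i, inst.atom_start + j)] = cls
    e_lj = e_coul = 0.0
    n = top.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            cls = separation.get((i, j)) or separation.get((j, i))
            if mol_of[i] == mol_of[j] and cls in (2, 3):
                continue
            r = np.linalg.norm(coords[i] - coords[j])
            s_lj = FUDGE_LJ if cls == 4 else 1.0
            s_qq = FUDGE_QQ if cls == 4 else 1.0
            e = math.sqrt(eps[i] * eps[j])
            if e > 0:
                sr6 = (0.5 * (sig[i] + sig[j]) / r) ** 6
                e_lj += s_lj * 4.0 * e * (sr6 * sr6 - sr6)
            e_coul += s_qq * KE * q[i] * q[j] / r
    eb, ea, ed = bonded_energy(frame, top)
    return eb + ea + ed + e_lj + e_coul


def test_total_energy_matches_naive_double_loop_oracle():
    top, frame = make_random_blend(seed=4, n_api=5, n_pol=3, box=5.0)
    open_frame = Frame(frame.coordinates)  # non-periodic: oracle has no images
    breakdown = total_energy(open_frame, top, coulomb_method="direct")
    assert breakdown.e_tot == pytest.approx(
        naive_total_energy(open_frame, top), rel=1e-9
    )
    # additivity of the reported terms
    parts = (
        breakdown.e_bond
        + breakdown.e_angle
        + breakdown.e_dih
        + breakdown.e_lj
        + breakdown.e_coul
    )
    assert breakdown.e_tot == pytest.approx(parts, rel=1e-12)


def test_single_uncharged_molecule_total_is_intramolecular_lj():
    from conftest import make_chain_molecule

    mol = make_chain_molecule("m", 6)
    top = SystemTopology([(mol, 1)])
    rng = np.random.default_rng(7)
    frame = Frame(rng.normal(0.0, 0.2, size=(6, 3)))
    b = total_energy(frame, top, coulomb_method="direct")
    assert b.e_coul == 0.0
    assert b.e_tot == pytest.approx(
        b.e_bond + b.e_lj, rel=1e-12
    )  # angles/dihedrals absent


# ---------------------------------------------------------------------------
# charge-zeroing decomposition


def cross_pair_coulomb(frame, top, members, box=None, cutoff=None):
    """Brute-force Coulomb between atom set ``members`` and the rest."""
    coords = frame.coordinates
    q = top.charges
    e = 0.0
    for i in np.flatnonzero(members):
        for j in np.flatnonzero(~members):
            d = coords[i] - coords[j]
            if box is not None:
                d = d - box * np.round(d / box)
            r = np.linalg.norm(d)
            if cutoff is not None and r > cutoff:
                continue
            e += KE * q[i] * q[j] / r
    return e


def test_zeroing_single_molecule_system_is_zero():
    from conftest import make_chain_molecule

    mol = make_chain_molecule("m", 4, charges=[0.3, -0.1, -0.1, -0.1])
    top = SystemTopology([(mol, 1)])
    frame = Frame(np.random.default_rng(1).normal(0.0, 0.2, size=(4, 3)))
    assert intermolecular_coulomb_by_zeroing(frame, top, 0, method="direct") == 0.0


@pytest.mark.parametrize("method", ["direct", "minimum-image"])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_zeroing_equals_cross_pair_oracle(method, seed):
    top, frame = make_random_blend(seed=seed, n_api=6, n_pol=4, box=4.0)
    box = frame.box if method == "minimum-image" else None
    cutoff = 0.9 if method == "minimum-image" else None
    if method == "direct":
        frame = Frame(frame.coordinates)
    for inst_index in (0, len(top.instances) - 1):
        members = top.atom_molecule == inst_index
        expected = cross_pair_coulomb(frame, top, members, box=box, cutoff=cutoff)
        got = intermolecular_coulomb_by_zeroing(
            frame, top, inst_index, method=method, cutoff=cutoff
        )
        assert got == pytest.approx(expected, abs=1e-6)


def test_zeroing_bilinear_identity_five_molecule_toy():
    # sum over molecules of E_cross = 2 x total intermolecular energy
    top, frame = make_random_blend(seed=9, n_api=3, n_pol=2, box=4.0)
    frame = Frame(frame.coordinates)
    per_mol = [
        intermolecular_coulomb_by_zeroing(frame, top, m, method="direct")
        for m in range(len(top.instances))
    ]
    total_inter = 0.0
    for m in range(len(top.instances)):
        members = top.atom_molecule == m
        total_inter += cross_pair_coulomb(frame, top, members)
    # the oracle above also counts each unordered pair twice
    assert sum(per_mol) == pytest.approx(total_inter, abs=1e-8)
    assert sum(per_mol) == pytest.approx(2.0 * (total_inter / 2.0), abs=1e-8)


def test_species_intermolecular_nonpolar_is_zero():
    from conftest import make_chain_molecule

    mol = make_chain_molecule("m", 3)  # zero charges
    top = SystemTopology([(mol, 5)])
    rng = np.random.default_rng(3)
    frame = Frame(rng.uniform(0.0, 3.0, size=(15, 3)), box=np.full(3, 3.0))
    assert species_intermolecular_coulomb(frame, top, "m", method="direct") == 0.0


@pytest.mark.parametrize("species", ["api", "pol"])
def test_species_intermolecular_equals_oracle(species):
    top, frame = make_random_blend(seed=21, n_api=4, n_pol=3, box=4.0)
    frame = Frame(frame.coordinates)
    got = species_intermolecular_coulomb(frame, top, species, method="direct")
    # oracle: all distinct-molecule pairs with at least one molecule of the species
    coords, q = frame.coordinates, top.charges
    mol_of = top.atom_molecule
    sp = np.array([top.instances[m].species for m in mol_of])
    expected = 0.0
    n = top.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            if mol_of[i] == mol_of[j]:
                continue
            if sp[i] != species and sp[j] != species:
                continue
            expected += KE * q[i] * q[j] / np.linalg.norm(coords[i] - coords[j])
    assert got == pytest.approx(expected, abs=1e-6)


def test_species_intermolecular_invariant_under_rigid_translation():
    top, frame = make_random_blend(seed=5, n_api=3, n_pol=2, box=4.0)
    open_frame = Frame(frame.coordinates)
    moved = Frame(frame.coordinates + np.array([1.7, -2.1, 0.4]))
    e0 = species_intermolecular_coulomb(open_frame, top, "api", method="direct")
    e1 = species_intermolecular_coulomb(moved, top, "api", method="direct")
    assert e1 == pytest.approx(e0, rel=1e-12)


def test_zeroing_rejects_bad_molecule_index():
    top, frame = make_random_blend(seed=0)
    with pytest.raises(IndexError):
        intermolecular_coulomb_by_zeroing(frame, top, 999)
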