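"""Unwrapping, MSD, Einstein diffusion fit, RMSF, replicate statistics."""

from __future__ import annotations

import math

import numpy as np
import pytest

from asdmix.constants import D_NM2_PS_TO_1E10_CM2_S
from asdmix.mobility import (
    MsdCurve,
    diffusion_coefficient,
    msd,
    replicate_stats,
    rmsf,
    unwrap,
)
from asdmix.model import AtomSpec, Frame, MoleculeTopology, SystemTopology, Trajectory
from asdmix.synthetic import gen_brownian, gen_harmonic


def single_particle_traj(positions, box=5.0, wrapped=True, dt=1.0):
    frames = [
        Frame(np.array([p]), box=np.full(3, box), time=i * dt, wrapped=wrapped)
        for i, p in enumerate(positions)
    ]
    return Trajectory(frames)


def particle_topology(n=1):
    mol = MoleculeTopology("p", [AtomSpec("P", "C", 1.0)])
    return SystemTopology([(mol, n)])


# ---------------------------------------------------------------------------
# unwrap


def test_unwrap_boundary_crossing_is_monotone():
    xs = [4.6, 4.8, 0.0, 0.2, 0.4]  # crosses +x boundary of a 5 nm box
    traj = unwrap(single_particle_traj([[x, 1.0, 1.0] for x in xs]))
    got = traj.coords[:, 0, 0]
    np.testing.assert_allclose(got, [4.6, 4.8, 5.0, 5.2, 5.4], atol=1e-12)
    assert not traj.wrapped


def test_unwrap_is_identity_on_unwrapped_input():
    traj = single_particle_traj([[1.0, 1.0, 1.0], [6.0, 1.0, 1.0]], wrapped=False)
    assert unwrap(traj) is traj


def test_wrap_then_unwrap_recovers_random_walk():
    rng = np.random.default_rng(8)
    box = 3.0
    steps = rng.normal(0.0, 0.2, size=(200, 4, 3))
    original = np.concatenate(
        [np.full((1, 4, 3), 1.5), 1.5 + np.cumsum(steps, axis=0)]
    )
    wrapped_frames = [
        Frame(np.mod(original[t], box), box=np.full(3, box), time=float(t), wrapped=True)
        for t in range(len(original))
    ]
    recovered = unwrap(Trajectory(wrapped_frames)).coords
    # unwrapping recovers shapes up to a constant image offset per atom
    offset = recovered[0] - original[0]
    np.testing.assert_allclose(recovered - offset, original, atol=1e-9)


def test_unwrap_rejects_half_box_jumps():
    traj = single_particle_traj([[0.1, 1.0, 1.0], [2.6, 1.0, 1.0]], box=5.0)
    with pytest.raises(ValueError, match="half a box edge"):
        unwrap(traj)


# ---------------------------------------------------------------------------
# MSD


def test_msd_static_molecules_identically_zero():
    top = particle_topology()
    traj = single_particle_traj([[1.0, 1.0, 1.0]] * 20, wrapped=False)
    curve = msd(traj, top, "p")
    np.testing.assert_allclose(curve.values, 0.0, atol=1e-12)


def test_msd_uniform_drift_closed_form():
    top = particle_topology()
    v = np.array([0.03, -0.01, 0.02])
    traj = single_particle_traj([list(1.0 + v * t) for t in range(50)], wrapped=False)
    curve = msd(traj, top, "p")
    expected = np.sum(v**2) * curve.lag_times**2
    np.testing.assert_allclose(curve.values, expected, rtol=1e-8, atol=1e-12)


def test_msd_requires_unwrapped_input():
    top = particle_topology()
    traj = single_particle_traj([[1.0, 1.0, 1.0]] * 5, wrapped=True)
    with pytest.raises(ValueError, match="unwrapped"):
        msd(traj, top, "p")


def test_msd_fft_matches_naive_multiple_origin_loop():
    rng = np.random.default_rng(4)
    n_frames, n_mol = 60, 3
    mol = MoleculeTopology("p", [AtomSpec("P", "C", 1.0)])
    top = SystemTopology([(mol, n_mol)])
    coords = np.cumsum(rng.normal(0, 0.1, size=(n_frames, n_mol, 3)), axis=0)
    traj = Trajectory(
        [Frame(coords[t], time=float(t), wrapped=False) for t in range(n_frames)]
    )
    curve = msd(traj, top, "p")
    naive = np.zeros(n_frames)
    for lag in range(1, n_frames):
        disp = coords[lag:] - coords[:-lag]
        naive[lag] = np.mean(np.sum(disp**2, axis=-1))
    np.testing.assert_allclose(curve.values, naive, rtol=1e-8, atol=1e-12)


def test_msd_strided_origins_match_explicit_subsample():
    rng = np.random.default_rng(14)
    coords = np.cumsum(rng.normal(0, 0.1, size=(40, 2, 3)), axis=0)
    mol = MoleculeTopology("p", [AtomSpec("P", "C", 1.0)])
    top = SystemTopology([(mol, 2)])
    traj = Trajectory(
        [Frame(coords[t], time=float(t), wrapped=False) for t in range(40)]
    )
    curve = msd(traj, top, "p", origin_stride=7)
    for lag in (1, 5, 20):
        origins = np.arange(0, 40 - lag, 7)
        disp = coords[origins + lag] - coords[origins]
        assert curve.values[lag] == pytest.approx(np.mean(np.sum(disp**2, -1)))


def test_msd_permutation_invariant_over_molecules():
    top, traj = gen_brownian(n_mol=6, d=1e-4, dt=1.0, n_frames=100, seed=2)
    base = msd(traj, top, "particle").values
    perm = np.random.default_rng(0).permutation(6)
    coords = traj.coords[:, perm, :]
    traj2 = Trajectory(
        [Frame(coords[t], time=float(t), wrapped=False) for t in range(len(traj))]
    )
    np.testing.assert_allclose(msd(traj2, top, "particle").values, base, rtol=1e-10)


# ---------------------------------------------------------------------------
# diffusion


def test_exact_linear_msd_recovers_unit_slope():
    lags = np.arange(100, dtype=float)  # ps
    curve = MsdCurve(lags, 6.0 * lags, n_molecules=1, n_origins=100 - lags)
    res = diffusion_coefficient(curve)
    # slope 6 nm^2/ps -> D = 1 nm^2/ps = 1e8 x 1e-10 cm^2/s
    assert res.d == pytest.approx(1.0 * D_NM2_PS_TO_1E10_CM2_S, rel=1e-12)
    assert res.fit_r2 == pytest.approx(1.0)


def test_static_input_gives_zero_diffusion():
    lags = np.arange(50, dtype=float)
    curve = MsdCurve(lags, np.zeros(50), 1, 50 - lags)
    assert diffusion_coefficient(curve).d == 0.0


def test_negative_slope_clamped_with_warning():
    lags = np.arange(50, dtype=float)
    curve = MsdCurve(lags, -0.1 * lags, 1, 50 - lags)
    with pytest.warns(UserWarning, match="negative"):
        assert diffusion_coefficient(curve).d == 0.0


def test_diffusion_needs_enough_lags():
    lags = np.arange(5, dtype=float)
    with pytest.raises(ValueError, match="10 lags"):
        diffusion_coefficient(MsdCurve(lags, lags, 1, 5 - lags))


def test_brownian_diffusion_recovery_small():
    d_in = 1e-8  # nm^2/ps, i.e. 1.0 in output units
    values = []
    for seed in range(3):
        top, traj = gen_brownian(n_mol=60, d=d_in, dt=2.0, n_frames=3000, seed=seed)
        values.append(diffusion_coefficient(msd(traj, top, "particle")).d)
    mean, _ = replicate_stats(values)
    assert mean == pytest.approx(d_in * D_NM2_PS_TO_1E10_CM2_S, rel=0.15)


# ---------------------------------------------------------------------------
# RMSF


def test_rigid_translation_gives_zero_rmsf():
    mol = MoleculeTopology(
        "m", [AtomSpec("C1", "C", 12.0), AtomSpec("C2", "C", 12.0)]
    )
    top = SystemTopology([(mol, 1)])
    base = np.array([[0.0, 0.0, 0.0], [0.2, 0.0, 0.0]])
    frames = [
        Frame(base + t * np.array([0.1, 0.05, 0.0]), time=float(t), wrapped=False)
        for t in range(10)
    ]
    res = rmsf(Trajectory(frames), top, "m")
    assert res.heavy_atom_mean == pytest.approx(0.0, abs=1e-12)


def test_two_frame_hand_value():
    # after COM centring, atom 1 sits at (0,0,0) then (0.2,0,0): RMSF 0.1 nm
    mol = MoleculeTopology(
        "m", [AtomSpec("C1", "C", 12.0), AtomSpec("C2", "C", 12.0)]
    )
    top = SystemTopology([(mol, 1)])
    # equal masses: COM stays at origin while atoms move +/-0.1 symmetric
    f0 = Frame(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]]), time=0.0, wrapped=False)
    f1 = Frame(np.array([[0.2, 0.0, 0.0], [-0.2, 0.0, 0.0]]), time=1.0, wrapped=False)
    res = rmsf(Trajectory([f0, f1]), top, "m")
    np.testing.assert_allclose(res.per_atom, [0.1, 0.1], atol=1e-12)


def test_harmonic_wells_recover_equipartition_value():
    k, kt = 1000.0, 2.494
    top, traj = gen_harmonic(n_atoms_per_mol=5, n_mol=10, k=k, kt=kt,
                             n_frames=4000, seed=6)
    res = rmsf(traj, top, "blob")
    assert res.heavy_atom_mean == pytest.approx(math.sqrt(3 * kt / k), rel=0.02)


def test_rmsf_ignores_com_drift():
    top0, traj0 = gen_harmonic(n_frames=500, seed=3, drift=0.0)
    topd, trajd = gen_harmonic(n_frames=500, seed=3, drift=0.2)
    r0 = rmsf(traj0, top0, "blob").heavy_atom_mean
    rd = rmsf(trajd, topd, "blob").heavy_atom_mean
    assert rd == pytest.approx(r0, abs=1e-12)


def test_rmsf_excludes_hydrogens_from_average():
    mol = MoleculeTopology(
        "m", [AtomSpec("C1", "C", 12.0), AtomSpec("H1", "H", 1.0)]
    )
    top = SystemTopology([(mol, 1)])
    rng = np.random.default_rng(2)
    frames = [
        Frame(rng.normal(0, 0.05, size=(2, 3)), time=float(t), wrapped=False)
        for t in range(50)
    ]
    res = rmsf(Trajectory(frames), top, "m")
    assert len(res.per_atom) == 1  # only the carbon


def test_rmsf_positive_for_nonconstant_trajectory():
    top, traj = gen_harmonic(n_frames=50, seed=9)
    assert rmsf(traj, top, "blob").heavy_atom_mean > 0


# ---------------------------------------------------------------------------
# replicate statistics


def test_replicate_stats_closed_forms():
    assert replicate_stats([1.0, 1.0, 1.0, 1.0]) == (1.0, 0.0)
    mean, std = replicate_stats([0.0, 2.0, 0.0, 2.0])
    assert mean == pytest.approx(1.0)
    assert std == pytest.approx(math.sqrt(4.0 / 3.0))  # sample (n-1) convention


def test_replicate_stats_permutation_invariant():
    vals = [0.3, 1.7, 0.9, 2.2]
    m1, s1 = replicate_stats(vals)
    m2, s2 = replicate_stats(list(reversed(vals)))
    assert m1 == pytest.approx(m2, rel=1e-15)
    assert s1 == pytest.approx(s2, rel=1e-12)


def test_replicate_stats_single_value_flagged():
    with pytest.warns(UserWarning, match="undefined"):
        mean, std = replicate_stats([3.0])
    assert mean == 3.0 and math.isnan(std)
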