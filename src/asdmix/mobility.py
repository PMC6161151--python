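"""Kinetic descriptors: translational diffusion and roto-vibrational RMSF.

Translational mobility is measured by the Einstein relation: the
mean-squared displacement (MSD) of molecular centres of mass, averaged over
molecules and over multiple time origins, grows as ``6 D tau`` in the
diffusive regime. ``D`` is reported in units of 1e-10 cm^2/s.

Roto-vibrational mobility is summarised by the RMSF: each molecule's
mass-weighted centre of mass is moved to the origin in every frame (no
rotational superposition, so rotation contributes), then each atom's
root-mean-square fluctuation about its own average position is computed and
averaged over the heavy (non-hydrogen) atoms of all molecules of the
species.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import D_NM2_PS_TO_1E10_CM2_S
from .model import Frame, SystemTopology, Trajectory

__all__ = [
    "MsdCurve",
    "DiffusionResult",
    "FluctuationResult",
    "unwrap",
    "com_positions",
    "msd",
    "diffusion_coefficient",
    "rmsf",
    "replicate_stats",
]


@dataclass(frozen=True)
class MsdCurve:
    lag_times: np.ndarray  # ps
    values: np.ndarray  # nm^2
    n_molecules: int
    n_origins: np.ndarray  # origins averaged per lag


@dataclass(frozen=True)
class DiffusionResult:
    d: float  # 1e-10 cm^2/s
    fit_window: tuple[float, float]  # ps
    fit_r2: float
    replicates: tuple[float, ...] | None = None
    mean: float | None = None
    std: float | None = None


@dataclass(frozen=True)
class FluctuationResult:
    per_atom: np.ndarray  # nm, heavy atoms of every molecule of the species
    heavy_atom_mean: float  # nm
    replicates: tuple[float, ...] | None = None
    mean: float | None = None
    std: float | None = None


def unwrap(traj: Trajectory) -> Trajectory:
    """Remove periodic-boundary jumps so displacements are continuous.

    Successive-frame displacements are mapped to the nearest image;
    valid only when no atom moves half a box edge between stored frames.
    Already-unwrapped input is returned unchanged.
    """
    if not traj.wrapped:
        return traj
    if traj.boxes is None:
        raise ValueError("cannot unwrap a trajectory without box information")
    coords = traj.coords
    boxes = traj.boxes
    out = np.empty_like(coords)
    out[0] = coords[0]
    for t in range(1, len(coords)):
        disp = coords[t] - coords[t - 1]
        shift = np.round(disp / boxes[t])
        disp -= boxes[t] * shift
        if np.any(np.abs(disp) >= 0.5 * boxes[t] * (1.0 - 1e-9)):
            raise ValueError(
                f"frame {t}: displacement reaches half a box edge; trajectory "
                "is sampled too sparsely to unwrap"
            )
        out[t] = out[t - 1] + disp
    frames = [
        Frame(out[t], box=traj[t].box, time=traj[t].time, wrapped=False)
        for t in range(len(coords))
    ]
    return Trajectory(frames)


def com_positions(
    traj: Trajectory, topology: SystemTopology, species: str
) -> np.ndarray:
    """Mass-weighted centre-of-mass positions, shape (n_frames, n_mol, 3)."""
    instances = topology.instances_of(species)
    coords = traj.coords
    out = np.empty((len(traj), len(instances), 3))
    for m, inst in enumerate(instances):
        idx = inst.atom_indices
        w = topology.masses[idx]
        out[:, m, :] = np.einsum("tai,a->ti", coords[:, idx, :], w) / w.sum()
    return out


def _msd_fft(r: np.ndarray) -> np.ndarray:
    """All-origin MSD of positions (n_frames, n_mol, 3) via FFT.

    Standard autocorrelation split: MSD(m) = S1(m) - 2 S2(m) with
    S2 the positional autocorrelation and S1 from a running sum of |r|^2.
    Returns the molecule-averaged curve, shape (n_frames,).
    """
    n, n_mol, _ = r.shape
    flat = r.reshape(n, n_mol * 3)
    size = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(flat, n=size, axis=0)
    acf = np.fft.irfft(f * np.conj(f), n=size, axis=0)[:n].real
    counts = (n - np.arange(n)).astype(float)
    s2 = acf.reshape(n, n_mol, 3).sum(axis=2) / counts[:, None]
    d = (r**2).sum(axis=2)  # (n, n_mol)
    # Q_m = 2 sum(D) - sum_{k<m} D_k - sum_{k>=n-m} D_k
    csum = np.concatenate([np.zeros((1, n_mol)), np.cumsum(d, axis=0)])
    total = csum[-1]
    m = np.arange(n)
    q = 2.0 * total[None, :] - csum[m] - (total[None, :] - csum[n - m])
    s1 = q / counts[:, None]
    return (s1 - 2.0 * s2).mean(axis=1)


def _msd_direct(r: np.ndarray, origin_stride: int) -> tuple[np.ndarray, np.ndarray]:
    """Direct multiple-time-origin MSD with strided origins."""
    n = r.shape[0]
    values = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for lag in range(1, n):
        origins = np.arange(0, n - lag, origin_stride)
        disp = r[origins + lag] - r[origins]
        values[lag] = np.mean(np.sum(disp**2, axis=-1))
        counts[lag] = len(origins)
    counts[0] = len(np.arange(0, n, origin_stride))
    return values, counts


def msd(
    traj: Trajectory,
    topology: SystemTopology,
    species: str,
    origin_stride: int = 1,
) -> MsdCurve:
    """Centre-of-mass MSD of a species, averaged over molecules and origins.

    Requires unwrapped coordinates. With ``origin_stride == 1`` every frame
    is a time origin (computed exactly via FFT); larger strides subsample
    the origins with a direct sum.
    """
    if traj.wrapped:
        raise ValueError("MSD requires an unwrapped trajectory (see unwrap())")
    if len(traj) < 2:
        raise ValueError("MSD needs at least two frames")
    if origin_stride < 1:
        raise ValueError("origin_stride must be >= 1")
    com = com_positions(traj, topology, species)
    n = com.shape[0]
    if origin_stride == 1:
        values = _msd_fft(com)
        counts = n - np.arange(n)
    else:
        values, counts = _msd_direct(com, origin_stride)
    values[0] = 0.0
    values = np.maximum(values, 0.0)  # guard FFT round-off at tiny lags
    lags = np.arange(n) * traj.dt
    return MsdCurve(
        lag_times=lags,
        values=values,
        n_molecules=com.shape[1],
        n_origins=np.asarray(counts),
    )


def diffusion_coefficient(
    curve: MsdCurve,
    fit_window: tuple[float, float] = (0.1, 0.5),
) -> DiffusionResult:
    """Least-squares Einstein fit D = slope/6 over a lag-fraction window.

    ``fit_window`` is a fraction of the maximum lag, default 10-50% — late
    enough to leave any ballistic/caged regime, early enough that the
    multiple-origin average retains statistics. The fit r^2 is reported so
    a non-diffusive curve is visible. A negative slope is clamped to
    D = 0 with a warning.
    """
    lags = np.asarray(curve.lag_times, dtype=float)
    if len(lags) < 10:
        raise ValueError("MSD curve must span at least 10 lags")
    lo, hi = fit_window
    if not (0 <= lo < hi <= 1):
        raise ValueError("fit_window fractions must satisfy 0 <= lo < hi <= 1")
    t_max = lags[-1]
    sel = (lags >= lo * t_max) & (lags <= hi * t_max)
    if sel.sum() < 2:
        raise ValueError("fit window selects fewer than 2 lags")
    x = lags[sel]
    y = np.asarray(curve.values)[sel]
    slope, intercept = np.polyfit(x, y, 1)
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    d_nm2_ps = slope / 6.0
    if d_nm2_ps < 0:
        warnings.warn("negative MSD slope; clamping diffusion coefficient to 0")
        d_nm2_ps = 0.0
    return DiffusionResult(
        d=d_nm2_ps * D_NM2_PS_TO_1E10_CM2_S,
        fit_window=(float(lo * t_max), float(hi * t_max)),
        fit_r2=r2,
    )


def rmsf(
    traj: Trajectory, topology: SystemTopology, species: str
) -> FluctuationResult:
    """Per-atom RMSF after per-molecule COM removal, heavy-atom averaged.

    For each molecule of the species, the mass-weighted centre of mass is
    subtracted frame by frame (conformation and orientation untouched);
    each atom's fluctuation is sqrt(<|r - <r>|^2>) over frames. The
    headline number averages the heavy (non-hydrogen) atoms of all
    molecules, unweighted.
    """
    if len(traj) < 2:
        raise ValueError("RMSF needs at least two frames")
    instances = topology.instances_of(species)
    coords = traj.coords
    per_atom: list[float] = []
    for inst in instances:
        idx = inst.atom_indices
        w = topology.masses[idx]
        sub = coords[:, idx, :]
        com = np.einsum("tai,a->ti", sub, w) / w.sum()
        centred = sub - com[:, None, :]
        mean_pos = centred.mean(axis=0)
        fluct = np.sqrt(np.mean(np.sum((centred - mean_pos) ** 2, axis=2), axis=0))
        heavy = np.array([topology.elements[g] != "H" for g in idx])
        if not heavy.any():
            warnings.warn(
                f"molecule {inst.index} of {species!r} has no heavy atoms; excluded"
            )
            continue
        per_atom.extend(fluct[heavy])
    if not per_atom:
        raise ValueError(f"no heavy atoms found for species {species!r}")
    arr = np.asarray(per_atom)
    return FluctuationResult(per_atom=arr, heavy_atom_mean=float(arr.mean()))


def replicate_stats(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample standard deviation (ddof=1) across replicate runs."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("replicate_stats needs at least one value")
    if arr.size < 2:
        warnings.warn("standard deviation undefined for a single replicate")
        return float(arr[0]), math.nan
    return float(arr.mean()), float(arr.std(ddof=1))
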