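"""Physical constants and unit conversions.

Internal units follow the GROMACS convention throughout the package:
length nm, time ps, mass amu, charge in elementary charges, energy kJ/mol.
Conversions to and from other unit systems happen only at I/O edges and in
the reporting helpers below.
"""

from __future__ import annotations

#: Coulomb constant 1/(4 pi eps0) in kJ mol^-1 nm e^-2.
COULOMB_CONSTANT: float = 138.935458

#: Boltzmann constant in kJ mol^-1 K^-1 (for converting temperatures to kT).
BOLTZMANN_KJ_MOL_K: float = 0.00831446261815324

#: 1 nm = 10 Angstrom.
ANGSTROM_PER_NM: float = 10.0
NM_PER_ANGSTROM: float = 0.1

#: Diffusion-coefficient conversion. 1 nm^2/ps = 1e-14 cm^2 / 1e-12 s
#: = 1e-2 cm^2/s = 1e8 x (1e-10 cm^2/s). Diffusion coefficients are
#: reported in units of 1e-10 cm^2/s, the natural scale for glassy blends.
D_NM2_PS_TO_1E10_CM2_S: float = 1.0e8
D_1E10_CM2_S_TO_NM2_PS: float = 1.0e-8

#: Amber/GAFF 1-4 scaling: Lennard-Jones divided by 2, Coulomb by 1.2.
FUDGE_LJ: float = 0.5
FUDGE_QQ: float = 1.0 / 1.2

#: IUPAC 2021 standard atomic weights (conventional values), amu.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "He": 4.002602,
    "Li": 6.94,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403163,
    "Ne": 20.1797,
    "Na": 22.98976928,
    "Mg": 24.305,
    "Al": 26.9815384,
    "Si": 28.085,
    "P": 30.973761998,
    "S": 32.06,
    "Cl": 35.45,
    "Ar": 39.95,
    "K": 39.0983,
    "Ca": 40.078,
    "Fe": 55.845,
    "Cu": 63.546,
    "Zn": 65.38,
    "Br": 79.904,
    "I": 126.90447,
}
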