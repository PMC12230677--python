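"""Physical constants, unit conversions, and element data.

Internal unit system is atomic units throughout (bohr, e, hartree).  File
I/O uses angstroms for coordinates and atomic units for multipoles.
"""

from __future__ import annotations

import numpy as np

#: CODATA 2018 Bohr radius in angstrom.
BOHR_TO_ANGSTROM: float = 0.529177210903
ANGSTROM_TO_BOHR: float = 1.0 / BOHR_TO_ANGSTROM

#: Hartree/e expressed in kcal mol^-1 e^-1 (potential unit used in reports).
HARTREE_TO_KCAL_PER_MOL: float = 627.5094740631

#: Default per-atom electron-density cutoff radius (angstrom); pair sums use
#: the *sum* of the two atoms' cutoff radii, i.e. 10 angstrom by default.
DEFAULT_CUTOFF_RADIUS_ANGSTROM: float = 5.0

#: Overlap-population threshold below which far pairs are dropped.
DEFAULT_OP_THRESHOLD: float = 1.0e-4

ELEMENT_SYMBOLS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn",
]

SYMBOL_TO_NUMBER = {s: z for z, s in enumerate(ELEMENT_SYMBOLS) if z > 0}

# Standard atomic weights averaged over natural isotope abundances (u),
# bundled so center-of-mass computation needs no network access.  Values for
# elements without a stable isotope are conventional-mass numbers.
ATOMIC_WEIGHTS = np.array([
    0.0,
    1.008, 4.0026, 6.94, 9.0122, 10.81, 12.011, 14.007, 15.999, 18.998,
    20.180, 22.990, 24.305, 26.982, 28.085, 30.974, 32.06, 35.45, 39.948,
    39.098, 40.078, 44.956, 47.867, 50.942, 51.996, 54.938, 55.845, 58.933,
    58.693, 63.546, 65.38, 69.723, 72.630, 74.922, 78.971, 79.904, 83.798,
    85.468, 87.62, 88.906, 91.224, 92.906, 95.95, 97.0, 101.07, 102.91,
    106.42, 107.87, 112.41, 114.82, 118.71, 121.76, 127.60, 126.90, 131.29,
    132.91, 137.33, 138.91, 140.12, 140.91, 144.24, 145.0, 150.36, 151.96,
    157.25, 158.93, 162.50, 164.93, 167.26, 168.93, 173.05, 174.97, 178.49,
    180.95, 183.84, 186.21, 190.23, 192.22, 195.08, 196.97, 200.59, 204.38,
    207.2, 208.98, 209.0, 210.0, 222.0,
])


def atomic_weight(z: int) -> float:
    """Standard atomic weight (u) for atomic number ``z``."""
    if not 1 <= z < len(ATOMIC_WEIGHTS):
        raise ValueError(f"no atomic weight tabulated for Z={z}")
    return float(ATOMIC_WEIGHTS[z])


def element_symbol(z: int) -> str:
    if not 1 <= z < len(ELEMENT_SYMBOLS):
        raise ValueError(f"unknown atomic number {z}")
    return ELEMENT_SYMBOLS[z]


def pair_weight(op: np.ndarray | float) -> np.ndarray | float:
    """Localization weight w_Ab = 2 tanh(2 OP_Ab) of an atom-image pair.

    This weight gates how much charge a pair may carry during resorption:
    it vanishes for non-overlapping pairs and saturates near 2 for strongly
    bonded pairs, which localizes the re-expansion to bonded neighbors.
    """
    return 2.0 * np.tanh(2.0 * np.asarray(op, dtype=float))
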