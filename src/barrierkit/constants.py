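"""Physical constants and per-element data tables.

Every unit conversion and element parameter used anywhere in the package
lives here; modules must not define their own copies.
"""

from __future__ import annotations

import scipy.constants as _sc

# --- unit conversions -------------------------------------------------------

HARTREE_TO_KCAL = 627.5094740631  # kcal/mol per Hartree (CODATA-derived)
KCAL_TO_J = _sc.calorie * 1000.0
CAL_TO_J = _sc.calorie

# --- fundamental constants (SI) --------------------------------------------

KB = _sc.k                # J/K
H_PLANCK = _sc.h          # J s
C_LIGHT = _sc.c           # m/s
N_A = _sc.N_A             # 1/mol
R_GAS = _sc.R             # J/(mol K)
ATM_PA = _sc.atm          # Pa

R_KCAL = R_GAS / KCAL_TO_J          # kcal/(mol K)
R_CAL = R_GAS / CAL_TO_J            # cal/(mol K)

AMU_KG = _sc.atomic_mass            # kg per amu
BOHR_TO_ANGSTROM = _sc.physical_constants["Bohr radius"][0] * 1e10

# Grimme's average molecular moment of inertia used in the free-rotor
# entropy interpolation (kg m^2).
B_AV = 1.0e-44

# --- periodic table ---------------------------------------------------------

ELEMENTS = (
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn"
).split()

ATOMIC_NUMBER = {sym: i + 1 for i, sym in enumerate(ELEMENTS)}

# Standard atomic weights (amu), common elements only; extend as needed.
ATOMIC_MASS = {
    "H": 1.00794, "He": 4.002602, "Li": 6.941, "Be": 9.012182, "B": 10.811,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998403, "Ne": 20.1797,
    "Na": 22.989769, "Mg": 24.305, "Al": 26.981539, "Si": 28.0855,
    "P": 30.973762, "S": 32.065, "Cl": 35.453, "Ar": 39.948, "K": 39.0983,
    "Ca": 40.078, "Br": 79.904, "I": 126.90447,
}

# Bondi van der Waals radii (Angstrom).  The C radius of 1.70 gives the
# conventional 3.4 A C-C contact sum.
VDW_RADII = {
    "H": 1.20, "He": 1.40, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Ne": 1.54, "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75, "Ar": 1.88,
    "Br": 1.85, "I": 1.98, "Na": 2.27, "K": 2.75, "Li": 1.82, "Mg": 1.73,
}

# Covalent radii (Angstrom), Cordero et al. consensus values; used only for
# distance-based bond perception.
COVALENT_RADII = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76,
    "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58, "Na": 1.66, "Mg": 1.41,
    "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Br": 1.20, "I": 1.39,
}

# Valence electron counts for EState valence-delta computation.
VALENCE_ELECTRONS = {
    "H": 1, "C": 4, "N": 5, "O": 6, "F": 7, "Si": 4, "P": 5, "S": 6,
    "Cl": 7, "Br": 7, "I": 7, "B": 3,
}

# Principal quantum number of the valence shell.
PRINCIPAL_QUANTUM_NUMBER = {
    "H": 1, "He": 1,
    "Li": 2, "Be": 2, "B": 2, "C": 2, "N": 2, "O": 2, "F": 2, "Ne": 2,
    "Na": 3, "Mg": 3, "Al": 3, "Si": 3, "P": 3, "S": 3, "Cl": 3, "Ar": 3,
    "K": 4, "Ca": 4, "Br": 4, "Kr": 4,
    "I": 5, "Xe": 5,
}

# Gasteiger-Marsili electronegativity polynomial coefficients (a, b, c) by
# orbital type; chi(q) = a + b q + c q^2.  Original 1980 parameterisation.
PEOE_PARAMS = {
    "H": (7.17, 6.24, -0.56),
    "C_sp3": (7.98, 9.18, 1.88),
    "C_sp2": (8.79, 9.32, 1.51),
    "C_sp": (10.39, 9.45, 0.73),
    "N_sp3": (11.54, 10.82, 1.36),
    "N_sp2": (12.87, 11.15, 0.85),
    "N_sp": (15.68, 11.70, -0.27),
    "O_sp3": (14.18, 12.92, 1.39),
    "O_sp2": (17.07, 13.79, 0.47),
    "F": (14.66, 13.85, 2.31),
    "Cl": (11.00, 9.69, 1.35),
    "Br": (10.08, 8.47, 1.16),
    "I": (9.90, 7.96, 0.96),
    "S": (10.14, 9.13, 1.38),
}

# Electronegativity of the hydrogen cation, used as the normalisation for H
# in the charge-transfer denominator (Gasteiger & Marsili's convention).
PEOE_H_CATION_CHI = 20.02
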