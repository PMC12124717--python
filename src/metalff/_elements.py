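"""Embedded element data: atomic numbers, masses, radii, metals, UFF LJ subset.

All tables are keyed by the capitalized element symbol.  Covalent radii follow
the Cordero-style single-bond compilation (Å); masses are isotopic-average
atomic weights (amu); van der Waals radii (Å) are used only to place synthetic
ESP grid shells.  The UFF table carries the nonbonded vdW distance x (Å, the
like-pair minimum-energy distance) and well depth D (kcal/mol) for the metals
a coordination chemist commonly parametrizes.
"""

from __future__ import annotations

ATOMIC_NUMBERS: dict[str, int] = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Sc": 21, "Ti": 22,
    "V": 23, "Cr": 24, "Mn": 25, "Fe": 26, "Co": 27, "Ni": 28, "Cu": 29,
    "Zn": 30, "Ga": 31, "Ge": 32, "As": 33, "Se": 34, "Br": 35, "Kr": 36,
    "Rb": 37, "Sr": 38, "Y": 39, "Zr": 40, "Nb": 41, "Mo": 42, "Tc": 43,
    "Ru": 44, "Rh": 45, "Pd": 46, "Ag": 47, "Cd": 48, "In": 49, "Sn": 50,
    "Sb": 51, "Te": 52, "I": 53, "Xe": 54, "Cs": 55, "Ba": 56, "La": 57,
    "Ce": 58, "Pr": 59, "Nd": 60, "Pm": 61, "Sm": 62, "Eu": 63, "Gd": 64,
    "Tb": 65, "Dy": 66, "Ho": 67, "Er": 68, "Tm": 69, "Yb": 70, "Lu": 71,
    "Hf": 72, "Ta": 73, "W": 74, "Re": 75, "Os": 76, "Ir": 77, "Pt": 78,
    "Au": 79, "Hg": 80, "Tl": 81, "Pb": 82, "Bi": 83, "Po": 84, "At": 85,
    "Rn": 86, "Fr": 87, "Ra": 88, "Ac": 89, "Th": 90, "Pa": 91, "U": 92,
    "Np": 93, "Pu": 94, "Am": 95, "Cm": 96,
}

MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.003, "Li": 6.941, "Be": 9.012, "B": 10.811,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.086, "P": 30.974,
    "S": 32.066, "Cl": 35.453, "Ar": 39.948, "K": 39.098, "Ca": 40.078,
    "Sc": 44.956, "Ti": 47.867, "V": 50.942, "Cr": 51.996, "Mn": 54.938,
    "Fe": 55.845, "Co": 58.933, "Ni": 58.693, "Cu": 63.546, "Zn": 65.38,
    "Ga": 69.723, "Ge": 72.630, "As": 74.922, "Se": 78.971, "Br": 79.904,
    "Kr": 83.798, "Rb": 85.468, "Sr": 87.62, "Y": 88.906, "Zr": 91.224,
    "Nb": 92.906, "Mo": 95.95, "Tc": 98.0, "Ru": 101.07, "Rh": 102.906,
    "Pd": 106.42, "Ag": 107.868, "Cd": 112.414, "In": 114.818, "Sn": 118.710,
    "Sb": 121.760, "Te": 127.60, "I": 126.904, "Xe": 131.293, "Cs": 132.905,
    "Ba": 137.327, "La": 138.905, "Ce": 140.116, "Pr": 140.908, "Nd": 144.242,
    "Pm": 145.0, "Sm": 150.36, "Eu": 151.964, "Gd": 157.25, "Tb": 158.925,
    "Dy": 162.500, "Ho": 164.930, "Er": 167.259, "Tm": 168.934, "Yb": 173.045,
    "Lu": 174.967, "Hf": 178.49, "Ta": 180.948, "W": 183.84, "Re": 186.207,
    "Os": 190.23, "Ir": 192.217, "Pt": 195.084, "Au": 196.967, "Hg": 200.592,
    "Tl": 204.38, "Pb": 207.2, "Bi": 208.980, "Po": 209.0, "At": 210.0,
    "Rn": 222.0, "Fr": 223.0, "Ra": 226.0, "Ac": 227.0, "Th": 232.038,
    "Pa": 231.036, "U": 238.029, "Np": 237.0, "Pu": 244.0, "Am": 243.0,
    "Cm": 247.0,
}

# Single-bond covalent radii, Å (Cordero-style compilation; low-spin values
# for Mn/Fe/Co where the compilation lists two).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76,
    "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58, "Na": 1.66, "Mg": 1.41,
    "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Sc": 1.70, "Ti": 1.60, "V": 1.53, "Cr": 1.39,
    "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22,
    "Ga": 1.22, "Ge": 1.20, "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16,
    "Rb": 2.20, "Sr": 1.95, "Y": 1.90, "Zr": 1.75, "Nb": 1.64, "Mo": 1.54,
    "Tc": 1.47, "Ru": 1.46, "Rh": 1.42, "Pd": 1.39, "Ag": 1.45, "Cd": 1.44,
    "In": 1.42, "Sn": 1.39, "Sb": 1.39, "Te": 1.38, "I": 1.39, "Xe": 1.40,
    "Cs": 2.44, "Ba": 2.15, "La": 2.07, "Ce": 2.04, "Pr": 2.03, "Nd": 2.01,
    "Pm": 1.99, "Sm": 1.98, "Eu": 1.98, "Gd": 1.96, "Tb": 1.94, "Dy": 1.92,
    "Ho": 1.92, "Er": 1.89, "Tm": 1.90, "Yb": 1.87, "Lu": 1.87, "Hf": 1.75,
    "Ta": 1.70, "W": 1.62, "Re": 1.51, "Os": 1.44, "Ir": 1.41, "Pt": 1.36,
    "Au": 1.36, "Hg": 1.32, "Tl": 1.45, "Pb": 1.46, "Bi": 1.48, "Po": 1.40,
    "At": 1.50, "Rn": 1.50, "Fr": 2.60, "Ra": 2.21, "Ac": 2.15, "Th": 2.06,
    "Pa": 2.00, "U": 1.96, "Np": 1.90, "Pu": 1.87, "Am": 1.80, "Cm": 1.69,
}

# van der Waals radii, Å (Bondi-style; generic fallback 1.8 for elements the
# compilation omits).  Used only for synthetic ESP shell placement.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "He": 1.40, "Li": 1.82, "C": 1.70, "N": 1.55, "O": 1.52,
    "F": 1.47, "Ne": 1.54, "Na": 2.27, "Mg": 1.73, "Si": 2.10, "P": 1.80,
    "S": 1.80, "Cl": 1.75, "Ar": 1.88, "K": 2.75, "Ni": 1.63, "Cu": 1.40,
    "Zn": 1.39, "Ga": 1.87, "As": 1.85, "Se": 1.90, "Br": 1.85, "Kr": 2.02,
    "Pd": 1.63, "Ag": 1.72, "Cd": 1.58, "In": 1.93, "Sn": 2.17, "Te": 2.06,
    "I": 1.98, "Xe": 2.16, "Pt": 1.75, "Au": 1.66, "Hg": 1.55, "Tl": 1.96,
    "Pb": 2.02, "U": 1.86,
}
VDW_DEFAULT = 1.80

_NONMETALS = {
    "H", "He", "B", "C", "N", "O", "F", "Ne", "Si", "P", "S", "Cl", "Ar",
    "Ge", "As", "Se", "Br", "Kr", "Sb", "Te", "I", "Xe", "At", "Rn",
}

#: Alkali, alkaline-earth, transition, post-transition metals and f-block.
METALS: frozenset[str] = frozenset(
    sym for sym in ATOMIC_NUMBERS if sym not in _NONMETALS
)

# UFF-style nonbonded parameters for metals: x = vdW distance (Å, like-pair
# minimum-energy distance), D = well depth (kcal/mol).
UFF_LJ: dict[str, tuple[float, float]] = {
    "Li": (2.451, 0.025), "Be": (2.745, 0.085), "Na": (2.983, 0.030),
    "Mg": (3.021, 0.111), "Al": (4.499, 0.505), "K": (3.812, 0.035),
    "Ca": (3.399, 0.238), "Sc": (3.295, 0.019), "Ti": (3.175, 0.017),
    "V": (3.144, 0.016), "Cr": (3.023, 0.015), "Mn": (2.961, 0.013),
    "Fe": (2.912, 0.013), "Co": (2.872, 0.014), "Ni": (2.834, 0.015),
    "Cu": (3.495, 0.005), "Zn": (2.763, 0.124), "Ga": (4.383, 0.415),
    "Rb": (4.114, 0.040), "Sr": (3.641, 0.235), "Y": (3.345, 0.072),
    "Zr": (3.124, 0.069), "Nb": (3.165, 0.059), "Mo": (3.052, 0.056),
    "Tc": (2.891, 0.048), "Ru": (2.963, 0.056), "Rh": (2.929, 0.053),
    "Pd": (2.899, 0.048), "Ag": (3.148, 0.036), "Cd": (2.848, 0.228),
    "In": (4.463, 0.599), "Sn": (4.392, 0.567), "Cs": (4.517, 0.045),
    "Ba": (3.703, 0.364), "La": (3.522, 0.017), "Ce": (3.556, 0.013),
    "Eu": (3.487, 0.008), "Gd": (3.368, 0.009), "Yb": (3.355, 0.228),
    "Lu": (3.640, 0.041), "Hf": (3.141, 0.072), "Ta": (3.170, 0.081),
    "W": (3.069, 0.067), "Re": (2.954, 0.066), "Os": (3.120, 0.037),
    "Ir": (2.840, 0.073), "Pt": (2.754, 0.080), "Au": (3.293, 0.039),
    "Hg": (2.705, 0.385), "Tl": (4.347, 0.680), "Pb": (4.297, 0.663),
    "Bi": (4.370, 0.518), "Th": (3.396, 0.026), "U": (3.395, 0.022),
}


def normalize_symbol(symbol: str) -> str:
    """Capitalize an element symbol and validate it against the table.

    Raises ``ValueError`` naming the symbol when it is unknown.
    """
    sym = symbol.strip().capitalize()
    if sym not in ATOMIC_NUMBERS:
        raise ValueError(f"unknown element symbol: {symbol!r}")
    return sym


def covalent_radius(symbol: str) -> float:
    return COVALENT_RADII[normalize_symbol(symbol)]


def vdw_radius(symbol: str) -> float:
    return VDW_RADII.get(normalize_symbol(symbol), VDW_DEFAULT)


def atomic_mass(symbol: str) -> float:
    return MASSES[normalize_symbol(symbol)]


def is_metal(symbol: str) -> bool:
    return normalize_symbol(symbol) in METALS
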