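"""Elemental property tables and physical constants.

The heuristic atomic properties used by the autocorrelation descriptors are
Pauling electronegativities, Cordero covalent radii, IUPAC group numbers and
nuclear charges.  Coverage is limited to the elements that occur in the
cyclometalated-iridium chemistry handled by this package; asking for anything
else raises a ``KeyError`` naming the element rather than silently returning
a placeholder.
"""

from __future__ import annotations

# symbol -> (Z, Pauling electronegativity, Cordero covalent radius / Angstrom,
#            IUPAC group number)
_ELEMENTS: dict[str, tuple[int, float, float, int]] = {
    "H":  (1, 2.20, 0.31, 1),
    "B":  (5, 2.04, 0.84, 13),
    "C":  (6, 2.55, 0.76, 14),
    "N":  (7, 3.04, 0.71, 15),
    "O":  (8, 3.44, 0.66, 16),
    "F":  (9, 3.98, 0.57, 17),
    "Si": (14, 1.90, 1.11, 14),
    "P":  (15, 2.19, 1.07, 15),
    "S":  (16, 2.58, 1.05, 16),
    "Cl": (17, 3.16, 1.02, 17),
    "Br": (35, 2.96, 1.20, 17),
    "I":  (53, 2.66, 1.39, 17),
    "Ir": (77, 2.20, 1.41, 9),
}


def element_row(symbol: str) -> tuple[int, float, float, int]:
    try:
        return _ELEMENTS[symbol]
    except KeyError:
        raise KeyError(
            f"no atomic property data for element {symbol!r}; "
            f"supported: {sorted(_ELEMENTS)}"
        ) from None


def atomic_number(symbol: str) -> int:
    return element_row(symbol)[0]


def electronegativity(symbol: str) -> float:
    return element_row(symbol)[1]


def covalent_radius(symbol: str) -> float:
    return element_row(symbol)[2]


def group_number(symbol: str) -> int:
    return element_row(symbol)[3]


# ---------------------------------------------------------------------------
# Physical constants (CODATA 2018)

#: hartree in electron volts
HARTREE_EV = 27.211386245988
#: atomic unit of time t0 = (4 pi eps0)^2 hbar^3 / (m_e e^4), in seconds
ATOMIC_TIME_S = 2.4188843265857e-17
#: fine-structure constant
FINE_STRUCTURE = 7.2973525693e-3
#: Boltzmann constant in hartree per kelvin
BOLTZMANN_HARTREE_PER_K = 3.166811563e-6
#: refractive index of DMSO (sodium D line, 20 C) for the Strickler-Berg step
DMSO_REFRACTIVE_INDEX = 1.4793
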