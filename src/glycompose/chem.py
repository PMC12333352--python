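"""Monoisotopic mass arithmetic on elemental formulas.

All masses in the package reduce to sums over this module's atomic mass
table, so that every residue and adduct delta is reproducible from first
principles (and cross-checkable against an independent table).
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping

# IUPAC monoisotopic atomic masses (Da), most abundant isotope.
_ATOMIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "Na": 22.9897692809,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "K": 38.96370668,
}

#: Mass of a bare proton (H atom minus one electron), Da.
PROTON_MASS = 1.00727646688
#: Electron rest mass, Da.
ELECTRON_MASS = 0.00054857990

WATER = {"H": 2, "O": 1}
WATER_MASS = 2 * _ATOMIC_MASS["H"] + _ATOMIC_MASS["O"]


def atomic_mass_table() -> Mapping[str, float]:
    """Return the monoisotopic atomic mass table (element symbol -> Da).

    The special keys ``proton`` and ``electron`` are included alongside
    the neutral-atom masses.
    """
    table = dict(_ATOMIC_MASS)
    table["proton"] = PROTON_MASS
    table["electron"] = ELECTRON_MASS
    return table


def formula_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass of an elemental formula given as element->count.

    Counts may be negative (formula differences). Unknown elements raise
    ``KeyError`` naming the offending symbol.
    """
    total = 0.0
    for element, count in formula.items():
        if count == 0:
            continue
        try:
            total += _ATOMIC_MASS[element] * count
        except KeyError:
            raise KeyError(f"unknown element {element!r} in formula") from None
    return total


def merge_formulas(*formulas: Mapping[str, int]) -> dict[str, int]:
    """Sum elemental formulas; zero-count elements are dropped."""
    acc: Counter[str] = Counter()
    for f in formulas:
        acc.update(f)
    return {el: n for el, n in acc.items() if n != 0}


def scale_formula(formula: Mapping[str, int], factor: int) -> dict[str, int]:
    return {el: n * factor for el, n in formula.items() if n * factor != 0}


_HILL_FIRST = ("C", "H")


def hill_formula(formula: Mapping[str, int]) -> str:
    """Render a formula string in Hill order (C, H, then alphabetical)."""
    parts = []
    rest = sorted(el for el in formula if el not in _HILL_FIRST and formula[el])
    for el in (*_HILL_FIRST, *rest):
        n = formula.get(el, 0)
        if n == 0:
            continue
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)
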