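"""Closed-form calculators for glycan composition and isomer space.

Composition space: the number of distinct monomer/modification count
vectors for a DP range (re-exported from :mod:`glycompose.enumeration`).

Isomer space: the number of distinct *linear* structures for a chain of
``d`` monomers of which ``H`` are hexoses (the rest pentoses), extending
Laine-style counting for hexose oligomers to mixed hexose/pentose chains.
The count factorises as

    I(d, H) = 2^d                    anomeric configurations
            * 2^(3d + H)             ring-carbon stereocentres
                                       (4 per hexose, 3 per pentose)
            * C(d, H)                monomer arrangements along the chain
            * 4^H * 3^(d-H)
              * ((d-H)/(3d) + H/(4d))  glycosidic linkage positions, with
                                       the terminal monomer (no incoming
                                       linkage) averaged over arrangements
            * 2^d                    ring forms (pyranose/furanose)

The bracketed rational always cancels to an integer: C(d,H)*(d-H)/d =
C(d-1,H) and C(d,H)*H/d = C(d-1,H-1) count the arrangements whose terminal
monomer is a pentose or a hexose respectively. All arithmetic is exact
big-integer; results exceed 64 bits well before DP 12. Modifications are
not counted (their placement constraints do not factorise).
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

from .enumeration import count_compositions  # noqa: F401  (re-export)

__all__ = ["count_compositions", "isomer_count", "isomer_count_total"]


def isomer_count(d: int, H: int) -> int:
    """Number of linear structural isomers for a chain of *d* monomers
    with *H* hexoses and *d - H* pentoses. Exact integer."""
    if d < 1:
        raise ValueError("d must be >= 1")
    if not 0 <= H <= d:
        raise ValueError(f"H must satisfy 0 <= H <= d, got H={H}, d={d}")
    value = (
        Fraction(2**d)
        * 2 ** (3 * d + H)
        * comb(d, H)
        * 4**H
        * 3 ** (d - H)
        * (Fraction(d - H, 3 * d) + Fraction(H, 4 * d))
        * 2**d
    )
    if value.denominator != 1:
        raise ArithmeticError(f"non-integral isomer count at d={d}, H={H}")
    return int(value)


def isomer_count_total(d: int) -> int:
    """Total linear isomers over all hexose/pentose contents at DP *d*."""
    return sum(isomer_count(d, H) for H in range(d + 1))
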