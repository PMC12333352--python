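"""Composition-space enumeration and its closed-form counter.

For a DP range [d, D], m enabled modification types and c monomer types,
the unfiltered composition space has size

    N = sum_{i=d}^{D} (i + 1)^(m + c - 1)

because at DP i the hexose count contributes (i+1) choices when two monomer
types are enabled (pentose count is determined) and each modification count
independently ranges 0..i. Enumeration reproduces this count exactly
(double sulfation, which extends the sulfate range to 0..2i, intentionally
breaks the equality and is applied only on request).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from .model import MODIFICATIONS, Composition, Label, Monomer, get_modification


def count_compositions(d: int, D: int, m: int, c: int) -> int:
    """Closed-form size of the unfiltered composition space.

    Parameters are the DP range [d, D], the number of enabled modification
    types m and the number of monomer types c (1 or 2).
    """
    if c not in (1, 2):
        raise ValueError(f"c must be 1 or 2, got {c}")
    if d < 1 or D < d or m < 0:
        raise ValueError("require d >= 1, D >= d, m >= 0")
    return sum((i + 1) ** (m + c - 1) for i in range(d, D + 1))


@dataclass(frozen=True)
class PredictParams:
    """User constraints for composition prediction.

    max_avg_mods is the maximum average number of modifications per
    monomer (hard-capped at 3); double_sulfate lets sulfate exceed one
    unit per monomer (range 0..2*DP instead of 0..DP).
    """

    dp_min: int
    dp_max: int
    monomers: Sequence[Monomer] = (Monomer.HEXOSE, Monomer.PENTOSE)
    modifications: Sequence[str] = ()
    max_avg_mods: float = 3.0
    double_sulfate: bool = False
    label: Optional[Label] = None

    def __post_init__(self):
        if self.dp_min < 1 or self.dp_max < self.dp_min:
            raise ValueError("require 1 <= dp_min <= dp_max")
        if not self.monomers:
            raise ValueError("monomer set must not be empty")
        if not 0 < self.max_avg_mods <= 3:
            raise ValueError("max_avg_mods must be in (0, 3]")
        mods = tuple(get_modification(m).key for m in self.modifications)
        if len(set(mods)) != len(mods):
            raise ValueError("duplicate modification in parameter set")
        object.__setattr__(self, "modifications", mods)
        object.__setattr__(self, "monomers", tuple(dict.fromkeys(self.monomers)))

    @property
    def n_monomer_types(self) -> int:
        return len(self.monomers)


def enumerate_compositions(params: PredictParams) -> Iterator[Composition]:
    """Yield the unfiltered composition space for *params*, lazily.

    Order is deterministic: DP ascending, hexose count descending,
    modification counts in nested alphabetical loops. Before filtering and
    with double sulfation off, the stream length equals
    :func:`count_compositions`.
    """
    mods = sorted(params.modifications)
    hex_on = Monomer.HEXOSE in params.monomers
    pent_on = Monomer.PENTOSE in params.monomers
    for dp in range(params.dp_min, params.dp_max + 1):
        if hex_on and pent_on:
            hex_counts: Iterable[int] = range(dp, -1, -1)
        elif hex_on:
            hex_counts = (dp,)
        else:
            hex_counts = (0,)
        for n_hex in hex_counts:
            ranges = []
            for key in mods:
                top = 2 * dp if (key == "sulfate" and params.double_sulfate) else dp
                ranges.append(range(top + 1))
            for counts in itertools.product(*ranges):
                mod_counts = {k: n for k, n in zip(mods, counts) if n}
                if mod_counts.get("deoxy", 0) > n_hex:
                    continue
                yield Composition(n_hex, dp - n_hex, mod_counts, params.label)


def modification_density(comp: Composition) -> float:
    """Average number of density-counting modification units per monomer.

    Deoxy and sialic-acid units are excluded from the numerator (they name
    as monomers); sialic-acid units are added to the denominator.
    """
    numer = sum(
        n for k, n in comp.mods.items() if MODIFICATIONS[k].counts_toward_density
    )
    denom = comp.dp + comp.count("neuac")
    return numer / denom if denom else float("inf")


def filter_density(
    comps: Iterable[Composition], max_avg: float
) -> Iterator[Composition]:
    """Keep compositions whose modification density is <= *max_avg*."""
    if not 0 < max_avg <= 3:
        raise ValueError("max_avg must be in (0, 3]")
    # tiny epsilon absorbs float division noise on exact boundary ratios
    eps = 1e-9
    return (c for c in comps if modification_density(c) <= max_avg + eps)
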