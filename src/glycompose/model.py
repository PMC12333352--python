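"""Core glycan data model: monomers, modifications, labels, compositions.

A *composition* is the multiset of monomer and modification counts in an
oligosaccharide, without linkage or stereochemical information. Hexose and
pentose are the fundamental monomer blocks; every functional group (sulfate,
N-acetyl, deoxy, sialic acid, ...) is carried as a count of mass deltas that
is not assigned to any particular monomer. Deoxyhexose and sialic acid are
displayed as monomers in names but enumerated as modifications.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional

from .chem import (
    WATER,
    WATER_MASS,
    formula_mass,
    hill_formula,
    merge_formulas,
    scale_formula,
)


class Monomer(str, Enum):
    """Base monomer kinds, distinguished by ring carbon count."""

    HEXOSE = "hexose"
    PENTOSE = "pentose"


#: Residue formulas (free sugar minus one water).
MONOMER_RESIDUE_FORMULA: dict[Monomer, dict[str, int]] = {
    Monomer.HEXOSE: {"C": 6, "H": 10, "O": 5},
    Monomer.PENTOSE: {"C": 5, "H": 8, "O": 4},
}

MONOMER_RESIDUE_MASS: dict[Monomer, float] = {
    m: formula_mass(f) for m, f in MONOMER_RESIDUE_FORMULA.items()
}


@dataclass(frozen=True)
class ModificationKind:
    """A modification applied to a composition as an elemental delta.

    anionic
        carries an exchangeable acidic proton (drives Na/K cation exchange
        and charge capacity in negative mode).
    counts_toward_density
        whether units enter the numerator of the modifications-per-monomer
        density filter.
    names_as_monomer
        displayed as a monomer term in names (deoxyhexose, sialic acid).
    """

    key: str
    display: str
    delta_formula: Mapping[str, int]
    anionic: bool = False
    counts_toward_density: bool = True
    names_as_monomer: bool = False

    @property
    def delta_mass(self) -> float:
        return formula_mass(self.delta_formula)

    def __repr__(self) -> str:  # keep test output readable
        return f"Mod({self.key})"


def _mods(*specs) -> dict[str, ModificationKind]:
    return {m.key: m for m in specs}


#: The built-in modification catalogue. AnhydroBridge, Dehydrated and
#: Unsaturated all correspond to loss of one water but are distinct names
#: for distinct structural features.
MODIFICATIONS: dict[str, ModificationKind] = _mods(
    ModificationKind("carboxylicacid", "CarboxylicAcid", {"H": -2, "O": 1}, anionic=True),
    ModificationKind("neuac", "NeuAc", {"C": 11, "H": 17, "N": 1, "O": 8},
                     anionic=True, counts_toward_density=False, names_as_monomer=True),
    ModificationKind("deoxy", "DeoxyHex", {"O": -1},
                     counts_toward_density=False, names_as_monomer=True),
    ModificationKind("phosphate", "Phosphate", {"H": 1, "P": 1, "O": 3}, anionic=True),
    ModificationKind("sulfate", "Sulfate", {"S": 1, "O": 3}, anionic=True),
    ModificationKind("nacetyl", "N-Acetyl", {"C": 2, "H": 3, "N": 1}),
    ModificationKind("oacetyl", "O-Acetyl", {"C": 2, "H": 2, "O": 1}),
    ModificationKind("omethyl", "O-Methyl", {"C": 1, "H": 2}),
    ModificationKind("anhydrobridge", "AnhydroBridge", {"H": -2, "O": -1}),
    ModificationKind("amino", "Amino", {"N": 1, "H": 1, "O": -1}),
    ModificationKind("dehydrated", "Dehydrated", {"H": -2, "O": -1}),
    ModificationKind("unsaturated", "Unsaturated", {"H": -2, "O": -1}),
)

_DISPLAY_TO_MOD = {m.display: m for m in MODIFICATIONS.values()}

#: Case-insensitive aliases accepted on the CLI and in configs.
MOD_ALIASES: dict[str, str] = {
    **{k: k for k in MODIFICATIONS},
    **{m.display.lower(): m.key for m in MODIFICATIONS.values()},
    "n-acetyl": "nacetyl",
    "o-acetyl": "oacetyl",
    "o-methyl": "omethyl",
    "sialicacid": "neuac",
    "sialic acid": "neuac",
    "deoxyhex": "deoxy",
    "anhydro-bridge": "anhydrobridge",
}


def get_modification(name: str) -> ModificationKind:
    """Resolve a modification by key, display name or alias."""
    key = MOD_ALIASES.get(name.strip().lower())
    if key is None:
        raise KeyError(f"unknown modification {name!r}")
    return MODIFICATIONS[key]


@dataclass(frozen=True)
class Label:
    """A derivatization label/linker, at most one per composition."""

    name: str
    delta_formula: Mapping[str, int]

    @property
    def delta_mass(self) -> float:
        return formula_mass(self.delta_formula)


#: Amino-pentyl linker: anomeric OH -> O-(CH2)5-NH2, net +C5H11N.
AMINOPENTYL = Label("aminopentyl", {"C": 5, "H": 11, "N": 1})

LABELS: dict[str, Label] = {AMINOPENTYL.name: AMINOPENTYL}


@dataclass(frozen=True)
class Composition:
    """Integer monomer/modification counts of a glycan composition.

    DP (degree of polymerization) counts hexose + pentose units only;
    sialic acid, although displayed as a monomer, does not increase DP.
    """

    n_hex: int = 0
    n_pent: int = 0
    mods: Mapping[str, int] = field(default_factory=dict)
    label: Optional[Label] = None

    def __post_init__(self):
        if self.n_hex < 0 or self.n_pent < 0:
            raise ValueError("monomer counts must be non-negative")
        clean = {k: v for k, v in self.mods.items() if v}
        for k, v in clean.items():
            if k not in MODIFICATIONS:
                raise KeyError(f"unknown modification {k!r}")
            if v < 0:
                raise ValueError(f"negative count for modification {k!r}")
        object.__setattr__(self, "mods", clean)
        if self.dp == 0 and self.label is None:
            raise ValueError("composition must contain at least one monomer")
        if clean.get("deoxy", 0) > self.n_hex:
            raise ValueError("deoxy count cannot exceed hexose count")

    @property
    def dp(self) -> int:
        return self.n_hex + self.n_pent

    def count(self, mod: str) -> int:
        return self.mods.get(mod, 0)

    @property
    def formula(self) -> dict[str, int]:
        parts = [
            scale_formula(MONOMER_RESIDUE_FORMULA[Monomer.HEXOSE], self.n_hex),
            scale_formula(MONOMER_RESIDUE_FORMULA[Monomer.PENTOSE], self.n_pent),
            WATER,
        ]
        for key, n in self.mods.items():
            parts.append(scale_formula(MODIFICATIONS[key].delta_formula, n))
        if self.label is not None:
            parts.append(self.label.delta_formula)
        return merge_formulas(*parts)

    @property
    def neutral_mass(self) -> float:
        """Neutral monoisotopic mass: residues + deltas + one water."""
        mass = (
            self.n_hex * MONOMER_RESIDUE_MASS[Monomer.HEXOSE]
            + self.n_pent * MONOMER_RESIDUE_MASS[Monomer.PENTOSE]
            + WATER_MASS
        )
        for key, n in self.mods.items():
            mass += MODIFICATIONS[key].delta_mass * n
        if self.label is not None:
            mass += self.label.delta_mass
        return mass

    @property
    def name(self) -> str:
        return canonical_name(self)

    def merge(self, other: "Composition") -> "Composition":
        """Glycosidic condensation: sum all counts (labels cannot merge)."""
        if self.label is not None and other.label is not None:
            raise ValueError("cannot merge two labelled compositions")
        mods = dict(self.mods)
        for k, v in other.mods.items():
            mods[k] = mods.get(k, 0) + v
        return Composition(
            self.n_hex + other.n_hex,
            self.n_pent + other.n_pent,
            mods,
            self.label or other.label,
        )

    def __repr__(self) -> str:
        return f"<Composition {self.name}>"


def canonical_name(comp: Composition) -> str:
    """Canonical composition name, e.g. ``"Hex1 N-Acetyl1"``.

    Deoxy units rename pairwise with hexoses as DeoxyHex (the displayed
    hexose count drops accordingly). Monomer terms (Hex, Pent, DeoxyHex)
    come first; the remaining components follow alphabetically by display
    name; counts are appended without a separator.
    """
    n_deoxy = comp.count("deoxy")
    terms: list[str] = []
    shown_hex = comp.n_hex - n_deoxy
    if shown_hex:
        terms.append(f"Hex{shown_hex}")
    if comp.n_pent:
        terms.append(f"Pent{comp.n_pent}")
    if n_deoxy:
        terms.append(f"DeoxyHex{n_deoxy}")
    rest = sorted(
        (MODIFICATIONS[k].display, n)
        for k, n in comp.mods.items()
        if k != "deoxy" and n
    )
    terms.extend(f"{disp}{n}" for disp, n in rest)
    if comp.label is not None:
        terms.append(f"[{comp.label.name}]")
    return " ".join(terms)


_TERM_RE = re.compile(r"^(?P<name>.+?)(?P<count>\d+)$")


def parse_name(text: str) -> Composition:
    """Parse a canonical composition name back into a :class:`Composition`.

    Inverse of :func:`canonical_name`; unknown component tokens are
    rejected with the offending token named.
    """
    n_hex = n_pent = 0
    mods: dict[str, int] = {}
    label: Optional[Label] = None
    for token in text.split():
        if token.startswith("[") and token.endswith("]"):
            lname = token[1:-1]
            if lname not in LABELS:
                raise ValueError(f"unknown label {lname!r}")
            label = LABELS[lname]
            continue
        m = _TERM_RE.match(token)
        if not m:
            raise ValueError(f"unparseable component {token!r}")
        name, count = m.group("name"), int(m.group("count"))
        if name == "Hex":
            n_hex += count
        elif name == "Pent":
            n_pent += count
        elif name == "DeoxyHex":
            n_hex += count
            mods["deoxy"] = mods.get("deoxy", 0) + count
        elif name in _DISPLAY_TO_MOD:
            key = _DISPLAY_TO_MOD[name].key
            mods[key] = mods.get(key, 0) + count
        else:
            raise ValueError(f"unknown component {name!r}")
    return Composition(n_hex, n_pent, mods, label)


def anionic_count(comp: Composition) -> int:
    """Number of anionic (exchangeable acidic proton) groups.

    Sulfate + phosphate + carboxylic acid + sialic acid carboxylate units;
    bounds the degree of Na/K cation exchange and deprotonation.
    """
    return sum(n for k, n in comp.mods.items() if MODIFICATIONS[k].anionic)
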