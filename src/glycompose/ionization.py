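"""Adduct expansion and theoretical m/z computation.

Neutral compositions are expanded to the ionic species expected under a
given polarity and ionization type. m/z arithmetic is electron-correct:
an adduct's mass delta is the sum of the neutral atoms gained/lost minus
``charge * m_e``, which is identical to proton-based bookkeeping
(±1.00727646 Da per proton gained/lost, +21.981944 Da per H→Na exchange,
+37.955882 Da per H→K exchange).

Cation exchange ([M-(k+z)H + kNa]^z-, etc.) replaces acidic protons on
anionic groups (sulfate, phosphate, carboxylate, sialic acid) by Na+/K+,
so such adducts are only generated for compositions carrying at least k
anionic groups. MALDI produces singly charged ions; ESI charge states run
up to min(max_charge, DP).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

from .chem import ELECTRON_MASS, formula_mass
from .model import Composition, anionic_count

logger = logging.getLogger(__name__)

#: Groups that may appear in an adduct name, with their neutral formulas.
_ION_GROUPS = {
    "H": {"H": 1},
    "Na": {"Na": 1},
    "K": {"K": 1},
    "Cl": {"Cl": 1},
    "NH4": {"N": 1, "H": 4},
}

_ADDUCT_RE = re.compile(r"^\[M(?P<terms>(?:[+-]\d*(?:NH4|Na|Cl|H|K))*)\](?P<z>\d*)(?P<sign>[+-])$")
_TERM_RE = re.compile(r"([+-])(\d*)(NH4|Na|Cl|H|K)")


@dataclass(frozen=True)
class AdductSpec:
    """A named ionic transformation of a neutral molecule."""

    name: str
    delta_mass: float
    charge: int
    requires_anionic: int = 0

    @property
    def polarity(self) -> str:
        return "negative" if self.charge < 0 else "positive"


def parse_adduct(name: str) -> AdductSpec:
    """Parse an adduct name like ``"[M-2H+Na]-"`` into an :class:`AdductSpec`.

    The mass delta is recomputed from the atomic masses of the named
    groups with electron correction; the anionic-group requirement is the
    number of protons exchanged for metal cations.
    """
    m = _ADDUCT_RE.match(name.replace(" ", ""))
    if not m:
        raise ValueError(f"unparseable adduct name {name!r}")
    z = int(m.group("z") or 1) * (1 if m.group("sign") == "+" else -1)
    delta = 0.0
    h_removed = 0
    for sign, count, group in _TERM_RE.findall(m.group("terms")):
        n = int(count or 1) * (1 if sign == "+" else -1)
        delta += n * formula_mass(_ION_GROUPS[group])
        if group == "H" and n < 0:
            h_removed += -n
    delta -= z * ELECTRON_MASS
    requires = max(0, h_removed - (abs(z) if z < 0 else 0))
    return AdductSpec(name=name, delta_mass=delta, charge=z, requires_anionic=requires)


def mz(comp: Composition, adduct: AdductSpec) -> float:
    """Theoretical m/z of *comp* under *adduct*.

    Raises ``ValueError`` if the composition lacks the anionic groups the
    adduct requires (callers doing bulk expansion skip instead).
    """
    if anionic_count(comp) < adduct.requires_anionic:
        raise ValueError(
            f"{adduct.name} requires {adduct.requires_anionic} anionic "
            f"group(s); {comp.name!r} has {anionic_count(comp)}"
        )
    return (comp.neutral_mass + adduct.delta_mass) / abs(adduct.charge)


@dataclass(frozen=True)
class IonRecord:
    """A (composition, adduct) pair with its theoretical m/z."""

    composition: Composition
    adduct: AdductSpec
    mz: float

    @property
    def charge(self) -> int:
        return self.adduct.charge


@dataclass(frozen=True)
class IonizationParams:
    """Polarity/ionization context for adduct expansion.

    adducts, when given, is an explicit list of adduct names that replaces
    the built-in defaults. cations selects the exchange metals. scan_range
    drops ions outside the instrument's m/z window.
    """

    polarity: str = "negative"
    ionization: str = "esi"
    adducts: Optional[Sequence[str]] = None
    max_charge: int = 3
    cations: Sequence[str] = ("Na", "K")
    scan_range: Optional[tuple[float, float]] = None
    max_exchange: int = 5

    def __post_init__(self):
        if self.polarity not in ("negative", "positive"):
            raise ValueError("polarity must be 'negative' or 'positive'")
        if self.ionization not in ("esi", "maldi"):
            raise ValueError("ionization must be 'esi' or 'maldi'")
        if self.max_charge < 1:
            raise ValueError("max_charge must be >= 1")


def _fmt(n: int, group: str) -> str:
    return f"{n if n > 1 else ''}{group}"


def default_adduct_names(params: IonizationParams, anionic: int, dp: int) -> list[str]:
    """Built-in adduct list for one composition.

    The exchange series is generated with k = 1..anionic (capped), per
    selected cation; base protonated/deprotonated species per reachable
    charge state.
    """
    zmax = 1 if params.ionization == "maldi" else max(1, min(params.max_charge, dp))
    k_max = min(anionic, params.max_exchange)
    names: list[str] = []
    if params.polarity == "negative":
        for z in range(1, zmax + 1):
            names.append(f"[M-{_fmt(z, 'H')}]{z if z > 1 else ''}-")
        if params.ionization == "esi" and zmax >= 1:
            names.append("[M+Cl]-")
        for cat in params.cations:
            for z in range(1, zmax + 1):
                for k in range(1, k_max + 1):
                    names.append(
                        f"[M-{_fmt(z + k, 'H')}+{_fmt(k, cat)}]{z if z > 1 else ''}-"
                    )
    else:
        for z in range(1, zmax + 1):
            names.append(f"[M+{_fmt(z, 'H')}]{z if z > 1 else ''}+")
        names.append("[M+Na]+")
        names.append("[M+K]+")
        if params.ionization == "esi":
            names.append("[M+NH4]+")
        for cat in params.cations:
            for z in range(1, zmax + 1):
                for k in range(1, k_max + 1):
                    names.append(
                        f"[M-{_fmt(k, 'H')}+{_fmt(k + z, cat)}]{z if z > 1 else ''}+"
                    )
    return names


def expand_adducts(
    comps: Iterable[Composition], params: IonizationParams
) -> Iterator[IonRecord]:
    """Cross compositions with applicable adducts, yielding ion records.

    Adducts whose anionic-group requirement a composition cannot meet are
    skipped (logged at debug level); ions outside the scan range are
    dropped.
    """
    explicit = (
        [parse_adduct(a) for a in params.adducts] if params.adducts is not None else None
    )
    if explicit is not None:
        wrong_pol = [a.name for a in explicit if a.polarity != params.polarity]
        if wrong_pol:
            raise ValueError(
                f"adducts {wrong_pol} do not match polarity {params.polarity!r}"
            )
        if not explicit:
            logger.warning("no applicable adducts for polarity %s", params.polarity)
            return
    lo, hi = params.scan_range if params.scan_range else (0.0, float("inf"))
    cache: dict[str, AdductSpec] = {}
    for comp in comps:
        anionic = anionic_count(comp)
        if explicit is not None:
            adducts = explicit
        else:
            adducts = []
            for name in default_adduct_names(params, anionic, comp.dp):
                spec = cache.get(name)
                if spec is None:
                    spec = cache[name] = parse_adduct(name)
                adducts.append(spec)
        neutral = comp.neutral_mass
        for adduct in adducts:
            if anionic < adduct.requires_anionic:
                logger.debug(
                    "skipping %s for %s: needs %d anionic group(s)",
                    adduct.name, comp.name, adduct.requires_anionic,
                )
                continue
            value = (neutral + adduct.delta_mass) / abs(adduct.charge)
            if not lo <= value <= hi:
                continue
            yield IonRecord(comp, adduct, value)


def ions_to_frame(records: Iterable[IonRecord]) -> pd.DataFrame:
    """Materialize ion records as the prediction table (one row per ion)."""
    rows = [
        {
            "composition": r.composition.name,
            "dp": r.composition.dp,
            "neutral_mass": r.composition.neutral_mass,
            "adduct": r.adduct.name,
            "charge": r.charge,
            "mz": r.mz,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["composition", "dp", "neutral_mass", "adduct", "charge", "mz"]
    )
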