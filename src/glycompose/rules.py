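"""Chemical-plausibility filtering of compositions.

A composition carries counts of modification units that are not assigned
to particular monomers. It is *feasible* under a rule set iff the units
can be distributed over the monomer instances such that every unit lands
on an allowed monomer kind, no monomer exceeds any per-kind capacity or
the per-monomer total cap, and no forbidden pair of modification kinds
shares a monomer. Monomers of the same kind are interchangeable, so the
decision is made over per-monomer *profiles* (multisets of modification
units a single monomer may carry) rather than labelled monomers; this
keeps the search exact and fast for DP up to 22.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Iterator, Mapping, Optional

import yaml

from .model import MODIFICATIONS, Composition, Monomer, get_modification

#: Sialic acid is displayed as a monomer and never assigned to a ring.
_UNASSIGNED = frozenset({"neuac"})


@dataclass(frozen=True)
class RuleSet:
    """Monomer/modification compatibility rules.

    allowed_on maps modification key -> monomer kinds it may occupy;
    capacity maps modification key -> max units per single monomer;
    pairwise_exclusions lists unordered pairs forbidden on one monomer;
    element_limits maps component key (``hex``, ``pent`` or a modification
    key) -> inclusive (min, max) total counts for the whole composition.
    """

    allowed_on: Mapping[str, frozenset[Monomer]] = field(default_factory=dict)
    capacity: Mapping[str, int] = field(default_factory=dict)
    pairwise_exclusions: frozenset[frozenset[str]] = frozenset()
    per_monomer_total_cap: int = 3
    element_limits: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        for k, cap in self.capacity.items():
            if cap < 1:
                raise ValueError(f"capacity for {k!r} must be >= 1")
        for pair in self.pairwise_exclusions:
            if len(pair) != 2:
                raise ValueError("exclusions must be unordered pairs")

    def allowed(self, mod: str) -> frozenset[Monomer]:
        return self.allowed_on.get(mod, frozenset(Monomer))

    def cap(self, mod: str) -> int:
        return self.capacity.get(mod, 1)

    def excluded(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.pairwise_exclusions

    def with_element_limits(self, limits: Mapping[str, tuple[int, int]]) -> "RuleSet":
        merged = dict(self.element_limits)
        merged.update(limits)
        return replace(self, element_limits=merged)


_BOTH = frozenset(Monomer)
_HEX_ONLY = frozenset({Monomer.HEXOSE})


def default_ruleset(double_sulfate: bool = False) -> RuleSet:
    """The package's built-in rule set (every entry overridable via YAML).

    Sulfate/phosphate/O-acetyl/O-methyl may sit on either monomer kind;
    the anhydro bridge, carboxylic acid (uronic acid C6 oxidation) and
    deoxygenation are hexose chemistry; carboxylic acid is incompatible
    with an anhydro bridge or deoxygenation on the same monomer (all
    modify C6), and N-acetyl/amino compete for the same amino position.
    """
    return RuleSet(
        allowed_on={
            "sulfate": _BOTH,
            "phosphate": _BOTH,
            "omethyl": _BOTH,
            "oacetyl": _BOTH,
            "nacetyl": _BOTH,
            "amino": _BOTH,
            "dehydrated": _BOTH,
            "unsaturated": _BOTH,
            "anhydrobridge": _HEX_ONLY,
            "carboxylicacid": _HEX_ONLY,
            "deoxy": _HEX_ONLY,
        },
        capacity={"sulfate": 2 if double_sulfate else 1},
        pairwise_exclusions=frozenset(
            {
                frozenset({"carboxylicacid", "anhydrobridge"}),
                frozenset({"carboxylicacid", "deoxy"}),
                frozenset({"nacetyl", "amino"}),
            }
        ),
        per_monomer_total_cap=3,
    )


def _check_element_limits(comp: Composition, rules: RuleSet) -> bool:
    totals = {"hex": comp.n_hex, "pent": comp.n_pent, **comp.mods}
    for key, (lo, hi) in rules.element_limits.items():
        try:
            n = totals.get(key, 0) if key in ("hex", "pent") else comp.count(
                get_modification(key).key
            )
        except KeyError:
            n = totals.get(key, 0)
        if not lo <= n <= hi:
            return False
    return True


@lru_cache(maxsize=None)
def _monomer_profiles(
    kind: Monomer,
    mods: tuple[str, ...],
    caps: tuple[int, ...],
    allowed: tuple[bool, ...],
    exclusions: frozenset[frozenset[str]],
    total_cap: int,
) -> tuple[tuple[int, ...], ...]:
    """All unit-count vectors a single monomer of *kind* may carry."""
    per_mod = [
        range(0, (caps[i] if allowed[i] else 0) + 1) for i in range(len(mods))
    ]
    out = []
    for vec in itertools.product(*per_mod):
        if sum(vec) > total_cap:
            continue
        present = [mods[i] for i, n in enumerate(vec) if n]
        if any(
            frozenset((a, b)) in exclusions
            for a, b in itertools.combinations(present, 2)
        ):
            continue
        out.append(vec)
    # profiles with more units first: speeds up the greedy descent
    out.sort(key=lambda v: -sum(v))
    return tuple(out)


def is_feasible(comp: Composition, rules: RuleSet) -> bool:
    """Exact feasibility of *comp* under *rules*.

    True iff the composition passes the element limits and its
    modification units admit a valid distribution over monomer instances.
    """
    if not _check_element_limits(comp, rules):
        return False
    mods = tuple(
        sorted(k for k, n in comp.mods.items() if n and k not in _UNASSIGNED)
    )
    if not mods:
        return True
    target = tuple(comp.count(k) for k in mods)
    caps = tuple(rules.cap(k) for k in mods)
    monomer_counts = {
        Monomer.HEXOSE: comp.n_hex,
        Monomer.PENTOSE: comp.n_pent,
    }
    profile_sets = {}
    for kind, n in monomer_counts.items():
        if n == 0:
            continue
        allowed = tuple(kind in rules.allowed(m) for m in mods)
        profile_sets[kind] = _monomer_profiles(
            kind, mods, caps, allowed, rules.pairwise_exclusions,
            rules.per_monomer_total_cap,
        )
    kinds = sorted(profile_sets, key=lambda k: k.value)

    def solve(kind_idx: int, remaining: tuple[int, ...]) -> bool:
        if all(r == 0 for r in remaining):
            return True
        if kind_idx == len(kinds):
            return False
        kind = kinds[kind_idx]
        n_monomers = monomer_counts[kind]
        profiles = profile_sets[kind]

        def place(p_idx: int, slots: int, rem: tuple[int, ...]) -> bool:
            if all(r == 0 for r in rem):
                return solve(kind_idx + 1, rem)
            if p_idx == len(profiles) or slots == 0:
                return solve(kind_idx + 1, rem)
            prof = profiles[p_idx]
            unit = sum(prof)
            if unit == 0:
                return solve(kind_idx + 1, rem)
            max_copies = min(
                slots, min(rem[i] // prof[i] for i in range(len(rem)) if prof[i])
            )
            for copies in range(max_copies, -1, -1):
                nxt = tuple(rem[i] - copies * prof[i] for i in range(len(rem)))
                if place(p_idx + 1, slots - copies, nxt):
                    return True
            return False

        return place(0, n_monomers, remaining)

    return solve(0, target)


def apply_rules(
    comps: Iterable[Composition], rules: RuleSet
) -> Iterator[Composition]:
    """Filter a composition stream by :func:`is_feasible`, order-preserving."""
    return (c for c in comps if is_feasible(c, rules))


# ---------------------------------------------------------------------------
# YAML (de)serialization and shipped presets


def ruleset_to_dict(rules: RuleSet) -> dict:
    return {
        "allowed_on": {
            k: sorted(m.value for m in v) for k, v in rules.allowed_on.items()
        },
        "capacity": dict(rules.capacity),
        "pairwise_exclusions": [sorted(p) for p in rules.pairwise_exclusions],
        "per_monomer_total_cap": rules.per_monomer_total_cap,
        "element_limits": {k: list(v) for k, v in rules.element_limits.items()},
    }


def ruleset_from_dict(data: Mapping) -> RuleSet:
    return RuleSet(
        allowed_on={
            get_modification(k).key: frozenset(Monomer(m) for m in v)
            for k, v in (data.get("allowed_on") or {}).items()
        },
        capacity={
            get_modification(k).key: int(v)
            for k, v in (data.get("capacity") or {}).items()
        },
        pairwise_exclusions=frozenset(
            frozenset(get_modification(m).key for m in pair)
            for pair in (data.get("pairwise_exclusions") or [])
        ),
        per_monomer_total_cap=int(data.get("per_monomer_total_cap", 3)),
        element_limits={
            str(k): (int(v[0]), int(v[1]))
            for k, v in (data.get("element_limits") or {}).items()
        },
    )


def load_ruleset(path) -> RuleSet:
    """Load a rule set from a YAML file (schema of :func:`ruleset_to_dict`)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ruleset_from_dict(data or {})


def save_ruleset(rules: RuleSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(ruleset_to_dict(rules), fh, sort_keys=True)


def load_preset(name: str) -> RuleSet:
    """Load a shipped preset (``n_glycan`` or ``o_glycan``).

    Presets start from the default rule set and only tighten it with
    compositional element limits.
    """
    from importlib.resources import files

    path = files("glycompose").joinpath(f"presets/{name}.yaml")
    if not path.is_file():
        raise KeyError(f"unknown preset {name!r}")
    data = yaml.safe_load(path.read_text())
    limits = {
        str(k): (int(v[0]), int(v[1]))
        for k, v in (data.get("element_limits") or {}).items()
    }
    return default_ruleset().with_element_limits(limits)
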