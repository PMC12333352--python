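"""Chemical-rule feasibility versus a brute-force assignment oracle."""

import itertools
import random

import pytest

from glycompose import (
    Composition,
    Monomer,
    PredictParams,
    RuleSet,
    apply_rules,
    default_ruleset,
    enumerate_compositions,
    is_feasible,
    load_preset,
    parse_name,
)
from glycompose.rules import load_ruleset, ruleset_from_dict, save_ruleset

HEX = Monomer.HEXOSE
PENT = Monomer.PENTOSE


def brute_force_feasible(comp: Composition, rules: RuleSet) -> bool:
    """Oracle: depth-first placement of individual modification units on
    labelled monomer instances, with symmetry pruning only."""
    monomers = [HEX] * comp.n_hex + [PENT] * comp.n_pent
    units = [
        k
        for k in sorted(comp.mods)
        if k != "neuac"
        for _ in range(comp.count(k))
    ]
    loads: list[dict] = [{} for _ in monomers]

    def ok(j, kind):
        if monomers[j] not in rules.allowed(kind):
            return False
        if loads[j].get(kind, 0) >= rules.cap(kind):
            return False
        if sum(loads[j].values()) >= rules.per_monomer_total_cap:
            return False
        return not any(
            rules.excluded(kind, other) for other, n in loads[j].items() if n
        )

    def dfs(i):
        if i == len(units):
            return True
        tried = set()
        for j in range(len(monomers)):
            state = (monomers[j], tuple(sorted(loads[j].items())))
            if state in tried:  # identical monomers are interchangeable
                continue
            tried.add(state)
            if not ok(j, units[i]):
                continue
            loads[j][units[i]] = loads[j].get(units[i], 0) + 1
            if dfs(i + 1):
                return True
            loads[j][units[i]] -= 1
        return False

    return dfs(0)


@pytest.mark.parametrize(
    "name,feasible,kwargs",
    [
        ("Hex1 N-Acetyl1 Amino1", False, {}),  # excluded pair, one monomer
        ("Hex2 N-Acetyl1 Amino1", True, {}),  # units on different monomers
        ("DeoxyHex1 Sulfate2", True, {"double_sulfate": True}),
        ("DeoxyHex1 Sulfate2", False, {}),  # sulfate capacity 1
        ("Hex1 CarboxylicAcid1 AnhydroBridge1", False, {}),  # both on C6
        ("Pent2 AnhydroBridge1", False, {}),  # hexose-only modification
    ],
)
def test_feasibility_examples(name, feasible, kwargs):
    rules = default_ruleset(**kwargs)
    comp = parse_name(name)
    assert is_feasible(comp, rules) is feasible
    assert brute_force_feasible(comp, rules) is feasible


def test_unmodified_compositions_always_kept(rules):
    comps = [parse_name("Hex3"), parse_name("Pent2"), parse_name("Hex1 Pent1")]
    assert list(apply_rules(comps, rules)) == comps


def test_per_monomer_total_cap():
    rules = RuleSet(per_monomer_total_cap=3)
    assert is_feasible(parse_name("Hex1 Sulfate1 O-Methyl1 O-Acetyl1"), rules)
    assert not is_feasible(
        parse_name("Hex1 Sulfate1 O-Methyl1 O-Acetyl1 Phosphate1"), rules
    )


def test_sialic_acid_not_assigned_to_monomers(rules):
    # NeuAc names as a monomer: it occupies no ring position, so a fully
    # loaded hexose plus NeuAc stays feasible.
    assert is_feasible(parse_name("Hex1 NeuAc1 Sulfate1"), rules)


_MOD_POOL = [
    "sulfate", "omethyl", "nacetyl", "amino", "oacetyl",
    "anhydrobridge", "carboxylicacid", "phosphate",
]


def random_ruleset(rng: random.Random) -> RuleSet:
    allowed = {}
    capacity = {}
    for mod in _MOD_POOL:
        allowed[mod] = frozenset(
            rng.sample([HEX, PENT], rng.randint(1, 2))
        )
        capacity[mod] = rng.randint(1, 2)
    pairs = frozenset(
        frozenset(p)
        for p in rng.sample(list(itertools.combinations(_MOD_POOL, 2)), 3)
    )
    return RuleSet(
        allowed_on=allowed,
        capacity=capacity,
        pairwise_exclusions=pairs,
        per_monomer_total_cap=rng.randint(1, 3),
    )


def test_oracle_equivalence_on_random_rulesets():
    """Exact agreement with brute-force unit placement, DP <= 3,
    four modification kinds, randomized rules."""
    rng = random.Random(20240917)
    params = PredictParams(
        1, 3, (HEX, PENT), ("sulfate", "omethyl", "nacetyl", "amino")
    )
    comps = list(enumerate_compositions(params))
    for _ in range(6):
        rules = random_ruleset(rng)
        for comp in comps:
            assert is_feasible(comp, rules) == brute_force_feasible(comp, rules), (
                comp, rules,
            )


def test_relaxation_monotonicity():
    """Enlarging allowed_on or capacities never breaks feasibility."""
    rng = random.Random(7)
    tight = random_ruleset(rng)
    loose = RuleSet(
        allowed_on={m: frozenset([HEX, PENT]) for m in _MOD_POOL},
        capacity={m: 3 for m in _MOD_POOL},
        pairwise_exclusions=tight.pairwise_exclusions,
        per_monomer_total_cap=3,
    )
    params = PredictParams(1, 3, (HEX, PENT), ("sulfate", "nacetyl", "amino"))
    for comp in enumerate_compositions(params):
        if is_feasible(comp, tight):
            assert is_feasible(comp, loose)


def test_element_limits():
    rules = load_preset("n_glycan")
    assert not is_feasible(parse_name("Hex2 N-Acetyl2"), rules)  # hex < 3
    assert is_feasible(parse_name("Hex3 N-Acetyl2"), rules)
    assert not is_feasible(parse_name("Hex3 Pent1 N-Acetyl2"), rules)


def test_presets_only_tighten(rules):
    preset = load_preset("o_glycan")
    params = PredictParams(1, 3, (HEX, PENT), ("nacetyl", "sulfate"))
    base = set(c.name for c in apply_rules(enumerate_compositions(params), rules))
    tightened = set(
        c.name for c in apply_rules(enumerate_compositions(params), preset)
    )
    assert tightened <= base


def test_ruleset_yaml_roundtrip(tmp_path, rules_ds):
    path = tmp_path / "rules.yaml"
    save_ruleset(rules_ds, path)
    again = load_ruleset(path)
    assert again == rules_ds


def test_ruleset_from_dict_validates():
    with pytest.raises(ValueError):
        ruleset_from_dict({"capacity": {"sulfate": 0}})
    with pytest.raises(KeyError):
        ruleset_from_dict({"allowed_on": {"quux": ["hexose"]}})
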