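"""The full composition-prediction pipeline.

Chains the stages: build the raw composition space for the DP range,
filter by modification density, filter by chemical rules, then (for ion
tables) expand adducts and apply the scan-range filter. Every stage is a
generator, so the pipeline streams: memory is flat in the number of rows.
"""

from __future__ import annotations

from typing import Iterator, Optional

import pandas as pd

from .enumeration import PredictParams, enumerate_compositions, filter_density
from .ionization import IonizationParams, expand_adducts, ions_to_frame
from .model import Composition
from .rules import RuleSet, apply_rules, default_ruleset


def predict_compositions(
    params: PredictParams, rules: Optional[RuleSet] = None
) -> Iterator[Composition]:
    """Stream the chemically plausible composition space for *params*."""
    if rules is None:
        rules = default_ruleset(double_sulfate=params.double_sulfate)
    stream = enumerate_compositions(params)
    stream = filter_density(stream, params.max_avg_mods)
    return apply_rules(stream, rules)


def predict_ions(
    params: PredictParams,
    ion_params: IonizationParams,
    rules: Optional[RuleSet] = None,
):
    """Stream ion records for the plausible composition space."""
    return expand_adducts(predict_compositions(params, rules), ion_params)


def composition_table(
    params: PredictParams, rules: Optional[RuleSet] = None
) -> pd.DataFrame:
    """Materialize the neutral composition table (name, counts, mass)."""
    rows = []
    for comp in predict_compositions(params, rules):
        row = {
            "name": comp.name,
            "dp": comp.dp,
            "hex": comp.n_hex,
            "pent": comp.n_pent,
            **{k: v for k, v in sorted(comp.mods.items())},
            "formula": _hill(comp),
            "neutral_mass": comp.neutral_mass,
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        mod_cols = [c for c in df.columns if c not in
                    ("name", "dp", "hex", "pent", "formula", "neutral_mass")]
        df[mod_cols] = df[mod_cols].fillna(0).astype(int)
    return df


def prediction_table(
    params: PredictParams,
    ion_params: IonizationParams,
    rules: Optional[RuleSet] = None,
) -> pd.DataFrame:
    """Materialize the ion prediction table used for annotation."""
    return ions_to_frame(predict_ions(params, ion_params, rules))


def _hill(comp: Composition) -> str:
    from .chem import hill_formula

    return hill_formula(comp.formula)
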