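"""Synthetic peak tables and spectra with known ground truth.

The generator plants peaks at the theoretical m/z of chosen
(composition, adduct) pairs with a relative mass error drawn from a
truncated normal (sigma = ppm_jitter, clipped at 2.5 sigma so a
3-sigma matching tolerance always recovers every planted peak), and adds
random decoy peaks that are rejected and resampled until they lie at
least 3 * ppm_jitter (with a 0.5 ppm floor) away from every planted
theoretical m/z. Same seed, same fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .ionization import IonRecord, parse_adduct
from .model import Composition, parse_name
from .ms2 import FragmentParams, Spectrum, fragment_space

_DECOY_PPM_FLOOR = 0.5


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic MS1 peak table.

    compositions are Composition objects or canonical names; adducts are
    adduct names applied to every composition (pairs whose anionic
    requirement the composition cannot meet are skipped).
    """

    compositions: Sequence[Union[Composition, str]]
    adducts: Sequence[str] = ("[M-H]-",)
    ppm_jitter: float = 1.0
    n_decoys: int = 50
    decoy_range: tuple[float, float] = (100.0, 1200.0)
    intensity_range: tuple[float, float] = (1e4, 1e7)
    seed: int = 0

    def __post_init__(self):
        if not self.compositions:
            raise ValueError("fixture needs at least one composition")
        if self.ppm_jitter < 0:
            raise ValueError("ppm_jitter must be >= 0")


def _resolve(comp: Union[Composition, str]) -> Composition:
    return parse_name(comp) if isinstance(comp, str) else comp


def _truncated_ppm(rng: np.random.Generator, sigma: float) -> float:
    if sigma == 0:
        return 0.0
    while True:
        eps = rng.normal(0.0, sigma)
        if abs(eps) <= 2.5 * sigma:
            return eps


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def planted_ions(spec: FixtureSpec) -> list[IonRecord]:
    """The theoretical ions a fixture plants (its annotation ground truth)."""
    ions = []
    for comp in spec.compositions:
        comp = _resolve(comp)
        from .model import anionic_count

        for name in spec.adducts:
            adduct = parse_adduct(name)
            if anionic_count(comp) < adduct.requires_anionic:
                continue
            ions.append(
                IonRecord(
                    comp, adduct,
                    (comp.neutral_mass + adduct.delta_mass) / abs(adduct.charge),
                )
            )
    if not ions:
        raise ValueError("no (composition, adduct) pair is applicable")
    return ions


def make_ms1_fixture(spec: FixtureSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build a synthetic MS1 peak table and its ground-truth table.

    Returns (peaks, truth): peaks has columns mz/intensity; truth maps
    every planted peak to its composition, adduct, charge and exact
    theoretical m/z.
    """
    rng = np.random.default_rng(spec.seed)
    ions = planted_ions(spec)
    truth_rows = []
    peak_rows = []
    theo = np.array([ion.mz for ion in ions])
    for ion in ions:
        eps = _truncated_ppm(rng, spec.ppm_jitter) * 1e-6
        obs = ion.mz * (1 + eps)
        intensity = _log_uniform(rng, *spec.intensity_range)
        peak_rows.append({"mz": obs, "intensity": intensity})
        truth_rows.append(
            {
                "mz": obs,
                "mz_theoretical": ion.mz,
                "composition": ion.composition.name,
                "adduct": ion.adduct.name,
                "charge": ion.charge,
            }
        )
    margin = max(3 * spec.ppm_jitter, _DECOY_PPM_FLOOR)
    for _ in range(spec.n_decoys):
        while True:
            m = rng.uniform(*spec.decoy_range)
            ppm_dist = np.abs(m - theo) / theo * 1e6
            if (ppm_dist >= margin).all():
                break
        peak_rows.append(
            {"mz": m, "intensity": _log_uniform(rng, *spec.intensity_range)}
        )
    peaks = pd.DataFrame(peak_rows).sort_values("mz", kind="stable").reset_index(drop=True)
    truth = pd.DataFrame(truth_rows).sort_values("mz", kind="stable").reset_index(drop=True)
    return peaks, truth


def make_ms2_fixture(
    precursor: Union[Composition, str],
    precursor_charge: int,
    n_fragments: int = 8,
    ppm_jitter: float = 1.0,
    seed: int = 0,
    params: FragmentParams = FragmentParams(),
    precursor_mz: Optional[float] = None,
    rt: Optional[float] = None,
) -> tuple[Spectrum, pd.DataFrame]:
    """Build a synthetic MS2 spectrum from a precursor's fragment space.

    Samples *n_fragments* distinct candidate fragment ions, jitters their
    m/z (truncated normal as for MS1) and returns the spectrum plus the
    fragment ground truth.
    """
    rng = np.random.default_rng(seed)
    precursor = _resolve(precursor)
    space = list(fragment_space(precursor, precursor_charge, params))
    if n_fragments > len(space):
        raise ValueError(
            f"requested {n_fragments} fragments but space has {len(space)}"
        )
    chosen = rng.choice(len(space), size=n_fragments, replace=False)
    mzs, intensities, truth_rows = [], [], []
    for idx in sorted(chosen):
        ion = space[idx]
        eps = _truncated_ppm(rng, ppm_jitter) * 1e-6
        obs = ion.mz * (1 + eps)
        mzs.append(obs)
        intensities.append(rng.uniform(0.05, 1.0))
        truth_rows.append(
            {
                "mz": obs,
                "mz_theoretical": ion.mz,
                "composition": ion.composition.name,
                "adduct": ion.adduct.name,
                "charge": ion.charge,
            }
        )
    spectrum = Spectrum(
        mz=np.array(mzs),
        intensity=np.array(intensities),
        ms_level=2,
        rt=rt,
        precursor_mz=precursor_mz,
        precursor_charge=precursor_charge,
    )
    truth = pd.DataFrame(truth_rows).sort_values("mz", kind="stable").reset_index(drop=True)
    return spectrum, truth
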