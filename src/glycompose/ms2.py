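"""MS2 spectrum extraction and precursor-constrained fragment annotation.

Fragments of a glycan precursor are modelled as sub-compositions: every
monomer and modification count may drop to any value between zero and its
precursor count (glycosidic chain shortening and losses of labile groups
such as sulfate), with up to a configurable number of extra water losses
(glycosidic cleavage plus in-source dehydration) and charge states up to
the precursor charge in the precursor polarity.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import ELECTRON_MASS, formula_mass
from .ionization import AdductSpec, IonRecord, parse_adduct
from .model import Composition, anionic_count
from .ms1 import annotate as _annotate_ms1

logger = logging.getLogger(__name__)


@dataclass
class Spectrum:
    """A centroided mass spectrum (MS1 or MS2).

    Peaks are kept sorted by m/z; intensities must be non-negative.
    Retention time is in seconds. Precursor metadata is present for MS2.
    """

    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1
    rt: Optional[float] = None
    precursor_mz: Optional[float] = None
    precursor_charge: Optional[int] = None
    id: str = ""

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if (self.intensity < 0).any():
            raise ValueError("negative intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)

    def normalized(self, floor: float = 0.0) -> "Spectrum":
        """Scale intensities to max 1 and drop peaks below *floor*."""
        if len(self) == 0:
            return self
        scaled = self.intensity / self.intensity.max()
        keep = scaled >= floor
        return Spectrum(
            self.mz[keep], scaled[keep], self.ms_level, self.rt,
            self.precursor_mz, self.precursor_charge, self.id,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mz": self.mz, "intensity": self.intensity})


Ms2Spectrum = Spectrum  # an MS2 spectrum is a Spectrum with ms_level == 2


def extract_ms2(
    spectra: Iterable[Spectrum],
    annotations: pd.DataFrame,
    mz_tol: float = 0.01,
    rt_window: Optional[float] = None,
    mz_col: str = "mz",
    rt_col: str = "rt",
) -> list[tuple[Spectrum, pd.DataFrame]]:
    """Retain MS2 spectra whose precursor matches an annotated MS1 peak.

    A spectrum is kept iff |precursor_mz - annotated peak m/z| <= mz_tol
    and, when both carry retention times and *rt_window* is set,
    |rt difference| <= rt_window. Each kept spectrum is paired with every
    matching annotation row.
    """
    ann = annotations.dropna(subset=["composition"]) if "composition" in annotations else annotations
    out: list[tuple[Spectrum, pd.DataFrame]] = []
    n_ms2 = 0
    for spec in spectra:
        if spec.ms_level != 2 or spec.precursor_mz is None:
            continue
        n_ms2 += 1
        sel = (ann[mz_col] - spec.precursor_mz).abs() <= mz_tol
        if rt_window is not None and rt_col in ann.columns and spec.rt is not None:
            sel &= (ann[rt_col] - spec.rt).abs() <= rt_window
        hits = ann.loc[sel]
        if len(hits):
            out.append((spec, hits.reset_index(drop=True)))
    if n_ms2 == 0:
        logger.warning("no MS2 spectra in source")
    return out


@dataclass(frozen=True)
class FragmentParams:
    """Options for fragment-space generation.

    extra_dehydrations allows additional water losses on top of the
    sub-composition (glycosidic B/Y cleavage and hydroxyl loss);
    cations enables Na/K exchange adducts on fragments (for precursors
    observed as exchanged species); bare_sulfate adds the HSO4- diagnostic
    fragment of labile sulfate loss.
    """

    extra_dehydrations: int = 2
    cations: Sequence[str] = ()
    bare_sulfate: bool = False
    max_exchange: int = 3


#: m/z of the bisulfate anion HSO4-, a diagnostic fragment of sulfated glycans.
BARE_SULFATE_MZ = formula_mass({"H": 1, "S": 1, "O": 4}) + ELECTRON_MASS
_BARE_SULFATE_ADDUCT = AdductSpec("HSO4-", 0.0, -1, 0)
_BARE_SULFATE_ION = IonRecord(
    Composition(n_hex=1, mods={"sulfate": 1}), _BARE_SULFATE_ADDUCT, BARE_SULFATE_MZ
)


def sub_compositions(precursor: Composition) -> Iterator[Composition]:
    """All component-wise sub-compositions of *precursor* with DP >= 1.

    The label, when present, may be retained or lost.
    """
    mods = sorted(precursor.mods)
    ranges = [range(precursor.n_hex + 1), range(precursor.n_pent + 1)]
    ranges += [range(precursor.count(k) + 1) for k in mods]
    labels = [None] if precursor.label is None else [None, precursor.label]
    for counts in itertools.product(*ranges):
        n_hex, n_pent, *mod_counts = counts
        if n_hex + n_pent < 1:
            continue
        mc = {k: n for k, n in zip(mods, mod_counts) if n}
        if mc.get("deoxy", 0) > n_hex:
            continue
        for label in labels:
            yield Composition(n_hex, n_pent, mc, label)


def fragment_space(
    precursor: Composition,
    precursor_charge: int,
    params: FragmentParams = FragmentParams(),
) -> Iterator[IonRecord]:
    """Candidate fragment ions for an annotated precursor.

    Sub-compositions x extra dehydrations x charges 1..|precursor charge|
    in the precursor polarity x proton-based (and optionally exchanged)
    adducts.
    """
    if precursor_charge == 0:
        raise ValueError("precursor charge must be nonzero")
    negative = precursor_charge < 0
    zmax = abs(precursor_charge)
    seen: set[tuple[str, str]] = set()
    for sub in sub_compositions(precursor):
        for extra in range(params.extra_dehydrations + 1):
            if extra:
                mods = dict(sub.mods)
                mods["dehydrated"] = mods.get("dehydrated", 0) + extra
                frag = Composition(sub.n_hex, sub.n_pent, mods, sub.label)
            else:
                frag = sub
            anionic = anionic_count(frag)
            for z in range(1, zmax + 1):
                names = []
                if negative:
                    names.append(f"[M-{z if z > 1 else ''}H]{z if z > 1 else ''}-")
                    for cat in params.cations:
                        for k in range(1, min(anionic, params.max_exchange) + 1):
                            names.append(
                                f"[M-{z + k if z + k > 1 else ''}H"
                                f"+{k if k > 1 else ''}{cat}]{z if z > 1 else ''}-"
                            )
                else:
                    names.append(f"[M+{z if z > 1 else ''}H]{z if z > 1 else ''}+")
                    for cat in params.cations:
                        for k in range(1, min(anionic, params.max_exchange) + 1):
                            names.append(
                                f"[M-{k if k > 1 else ''}H"
                                f"+{z + k if z + k > 1 else ''}{cat}]{z if z > 1 else ''}+"
                            )
                for name in names:
                    adduct = parse_adduct(name)
                    if anionic < adduct.requires_anionic:
                        continue
                    key = (frag.name, name)
                    if key in seen:
                        continue
                    seen.add(key)
                    value = (frag.neutral_mass + adduct.delta_mass) / z
                    yield IonRecord(frag, adduct, value)
    if params.bare_sulfate and negative and precursor.count("sulfate"):
        yield _BARE_SULFATE_ION


def annotate_ms2(
    spectrum: Spectrum,
    precursor_annotations: pd.DataFrame,
    tol_ppm: float,
    params: FragmentParams = FragmentParams(),
    intensity_floor: Optional[float] = None,
) -> pd.DataFrame:
    """Annotate fragment peaks of an extracted MS2 spectrum.

    The fragment space is the union over all precursor annotations (rows
    with canonical composition names and charges); each output row records
    which precursor annotation it derives from. Intensities can first be
    normalized to max 1 and floored.
    """
    from .model import parse_name

    if intensity_floor is not None:
        spectrum = spectrum.normalized(floor=intensity_floor)
    peaks = spectrum.to_frame()
    results = []
    for _, row in precursor_annotations.iterrows():
        comp = parse_name(row["composition"])
        charge = int(row.get("charge") or spectrum.precursor_charge or -1)
        ions = list(fragment_space(comp, charge, params))
        ann = _annotate_ms1(peaks, ions, tol_ppm=tol_ppm, keep_unmatched=False)
        ann.insert(0, "precursor_composition", row["composition"])
        ann.insert(1, "precursor_adduct", row.get("adduct", ""))
        results.append(ann)
    if not results:
        return pd.DataFrame()
    out = pd.concat(results, ignore_index=True)
    return out.sort_values(["mz", "precursor_composition", "composition"],
                           kind="stable").reset_index(drop=True)
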