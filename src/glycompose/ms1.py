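"""MS1 peak annotation against a theoretical ion table.

Experimental peaks match a theoretical ion when the relative mass error
|(observed - theoretical)/theoretical| * 1e6 is within the ppm tolerance.
Matching is performed with a sorted theoretical m/z index and binary
search over the window bounds, so annotation stays fast for prediction
tables with 10^5-10^6 rows. The reported ppm error is signed:
(observed - theoretical)/theoretical * 1e6.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .ionization import IonRecord, ions_to_frame

logger = logging.getLogger(__name__)

#: Tolerance presets (ppm) for common instrument setups.
TOLERANCE_PRESETS = {
    "orbitrap-pos": 1.5,
    "orbitrap-neg": 2.0,
    "orbitrap-ms2": 3.0,
    "qtof": 15.0,
}
DEFAULT_PPM = 5.0

_ANNOT_COLS = ["composition", "adduct", "charge", "mz_theoretical", "ppm_error"]


def _ion_frame(ions: Union[pd.DataFrame, Iterable[IonRecord]]) -> pd.DataFrame:
    if not isinstance(ions, pd.DataFrame):
        ions = ions_to_frame(ions)
    if "mz" not in ions.columns:
        raise ValueError("ion table lacks an 'mz' column")
    return ions


def annotate(
    peaks: pd.DataFrame,
    ions: Union[pd.DataFrame, Iterable[IonRecord]],
    tol_ppm: Optional[float] = DEFAULT_PPM,
    tol_da: Optional[float] = None,
    mz_col: str = "mz",
    keep_unmatched: bool = True,
) -> pd.DataFrame:
    """Annotate a peak table against theoretical ions.

    Returns a long-format table: one row per (peak, composition, adduct)
    match, carrying the original peak columns plus composition, adduct,
    charge, theoretical m/z and signed ppm error. With *keep_unmatched*,
    peaks without any match appear once with empty annotation fields.
    Either *tol_ppm* (relative) or *tol_da* (absolute) must be given.
    """
    if mz_col not in peaks.columns:
        raise ValueError(f"peak table has no {mz_col!r} column")
    if tol_da is None and (tol_ppm is None or tol_ppm <= 0):
        raise ValueError("tolerance must be positive")
    ions = _ion_frame(ions)

    peaks = peaks.reset_index(drop=True)
    peaks = peaks.assign(_peak_order=np.arange(len(peaks)))
    obs = peaks[mz_col].to_numpy(dtype=float)
    if np.isnan(obs).any():
        raise ValueError(f"non-numeric values in peak column {mz_col!r}")

    order = np.argsort(ions["mz"].to_numpy(), kind="stable")
    theo = ions["mz"].to_numpy()[order]

    if tol_da is not None:
        lo_bound, hi_bound = obs - tol_da, obs + tol_da
    else:
        # |obs - t| / t <= tol  <=>  obs/(1+tol) <= t <= obs/(1-tol)
        rel = tol_ppm * 1e-6
        lo_bound, hi_bound = obs / (1 + rel), obs / (1 - rel)
    lo = np.searchsorted(theo, lo_bound, side="left")
    hi = np.searchsorted(theo, hi_bound, side="right")

    peak_idx: list[int] = []
    ion_idx: list[int] = []
    for i, (a, b) in enumerate(zip(lo, hi)):
        for j in range(a, b):
            peak_idx.append(i)
            ion_idx.append(order[j])

    matched = peaks.iloc[peak_idx].reset_index(drop=True)
    ion_rows = ions.iloc[ion_idx].reset_index(drop=True)
    matched["composition"] = ion_rows["composition"]
    matched["adduct"] = ion_rows["adduct"]
    matched["charge"] = ion_rows["charge"]
    matched["mz_theoretical"] = ion_rows["mz"]
    matched["ppm_error"] = (
        (matched[mz_col] - matched["mz_theoretical"]) / matched["mz_theoretical"] * 1e6
    )

    if keep_unmatched:
        unmatched_mask = np.ones(len(peaks), dtype=bool)
        if peak_idx:
            unmatched_mask[np.unique(peak_idx)] = False
        unmatched = peaks.loc[unmatched_mask].copy()
        for col in _ANNOT_COLS:
            unmatched[col] = np.nan
        out = pd.concat([matched, unmatched], ignore_index=True)
    else:
        out = matched
    out = out.sort_values(
        ["_peak_order", "composition"], kind="stable", na_position="last"
    ).reset_index(drop=True)
    return out.drop(columns=["_peak_order"])


def collapse(rows: pd.DataFrame, mz_col: str = "mz") -> pd.DataFrame:
    """Collapse a long annotation table to one row per peak.

    Annotation strings ("composition: adduct") are concatenated with
    "; " in alphabetical order; n_annotations counts the matches.
    """
    if "n_annotations" in rows.columns:
        raise ValueError("input already collapsed")
    if "composition" not in rows.columns:
        raise ValueError("not an annotation table (no 'composition' column)")
    peak_cols = [c for c in rows.columns if c not in _ANNOT_COLS]
    out_rows = []
    for _, group in rows.groupby(mz_col, sort=True):
        names = sorted(
            f"{c}: {a}"
            for c, a in zip(group["composition"], group["adduct"])
            if isinstance(c, str)
        )
        base = group.iloc[0][peak_cols].to_dict()
        base["annotations"] = "; ".join(names)
        base["n_annotations"] = len(names)
        out_rows.append(base)
    return pd.DataFrame(out_rows, columns=peak_cols + ["annotations", "n_annotations"])


def crossref_local_db(
    rows: pd.DataFrame, db_path, name_col: str = "composition", id_col: str = "id"
) -> pd.DataFrame:
    """Left-join composition IDs from a local tab-separated database.

    The TSV must have a header with at least *name_col* and *id_col*
    columns keyed by canonical composition name. Duplicate keys are
    concatenated with "; " (a warning is logged).
    """
    try:
        db = pd.read_csv(db_path, sep="\t", dtype=str)
    except Exception as exc:  # pandas raises with line context
        raise ValueError(f"malformed database file {db_path}: {exc}") from exc
    for col in (name_col, id_col):
        if col not in db.columns:
            raise ValueError(f"database file lacks column {col!r}")
    if db[name_col].duplicated().any():
        dups = db[name_col][db[name_col].duplicated()].unique()
        logger.warning("duplicate database keys: %s", ", ".join(map(str, dups)))
        db = (
            db.groupby(name_col, as_index=False)
            .agg({id_col: lambda s: "; ".join(s.astype(str))})
        )
    merged = rows.merge(
        db[[name_col, id_col]].rename(columns={id_col: "db_id"}),
        how="left",
        left_on="composition",
        right_on=name_col,
    )
    if name_col != "composition" and name_col in merged.columns:
        merged = merged.drop(columns=[name_col])
    return merged
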