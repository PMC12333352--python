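"""File-format adapters: delimited peak tables and mzML spectra.

mzML reading is a streaming parser on lxml's incremental iterparse
(constant memory in the number of spectra) handling the standard CV
params: MS level, scan start time, precursor selected ion and charge,
and 32/64-bit float peak arrays with no or zlib compression. A matching
minimal mzML writer is provided for synthetic fixtures, so the reader
can be exercised without external data.
"""

from __future__ import annotations

import base64
import logging
import struct
import zlib
from typing import Iterable, Iterator, Optional
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd
from lxml import etree

from .ms2 import Spectrum

logger = logging.getLogger(__name__)


def read_peak_table(
    path, mz_col: str = "mz", sep: Optional[str] = None
) -> pd.DataFrame:
    """Read a delimited peak/feature table (comma or tab, sniffed).

    A header row is required; the m/z column must parse as numbers (the
    first offending row is named in the error). Row order is preserved.
    """
    if sep is None:
        with open(path) as fh:
            first = fh.readline()
        sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
    df = pd.read_csv(path, sep=sep)
    if mz_col not in df.columns:
        raise ValueError(
            f"peak table {path} has no {mz_col!r} column (found: {list(df.columns)})"
        )
    parsed = pd.to_numeric(df[mz_col], errors="coerce")
    if parsed.isna().any():
        row = int(parsed.index[parsed.isna()][0]) + 2  # 1-based + header
        raise ValueError(f"non-numeric m/z value at line {row} of {path}")
    df[mz_col] = parsed
    return df


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a table as UTF-8 delimited text.

    m/z and mass columns are printed at 6 decimals, ppm errors at 2;
    '.' decimal separator, no thousands separators.
    """
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            digits = 2 if "ppm" in col else 6
            out[col] = out[col].map(
                lambda v, d=digits: "" if pd.isna(v) else f"{v:.{d}f}"
            )
    out.to_csv(path, sep=sep, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# mzML


_ACC_MS_LEVEL = "MS:1000511"
_ACC_PROFILE = "MS:1000128"
_ACC_RT = "MS:1000016"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_CHARGE = "MS:1000041"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def _local(tag) -> str:
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _cv_params(elem) -> dict[str, dict]:
    """accession -> {'value': ..., 'unit': ...} over direct cvParam children."""
    out = {}
    for child in elem:
        if _local(child.tag) == "cvParam":
            out[child.get("accession")] = {
                "value": child.get("value", ""),
                "unit": child.get("unitName", ""),
            }
    return out


def _decode_array(bda) -> np.ndarray:
    params = _cv_params(bda)
    dtype = "<f4" if _ACC_F32 in params else "<f8"
    payload = b""
    for child in bda:
        if _local(child.tag) == "binary" and child.text:
            payload = base64.b64decode(child.text)
    if _ACC_ZLIB in params:
        payload = zlib.decompress(payload)
    return np.frombuffer(payload, dtype=dtype).astype(float)


def _parse_spectrum(elem) -> Spectrum:
    params = _cv_params(elem)
    ms_level = int(params[_ACC_MS_LEVEL]["value"]) if _ACC_MS_LEVEL in params else 1
    if _ACC_PROFILE in params:
        logger.warning(
            "spectrum %s is profile mode; centroided data expected",
            elem.get("id", "?"),
        )
    rt = prec_mz = prec_z = None
    mz_arr = intensity_arr = np.empty(0)
    for scan in elem.iter():
        name = _local(scan.tag)
        if name == "scan":
            p = _cv_params(scan)
            if _ACC_RT in p:
                rt = float(p[_ACC_RT]["value"])
                if p[_ACC_RT]["unit"] == "minute":
                    rt *= 60.0
        elif name == "selectedIon":
            p = _cv_params(scan)
            if _ACC_SELECTED_MZ in p:
                prec_mz = float(p[_ACC_SELECTED_MZ]["value"])
            if _ACC_CHARGE in p:
                prec_z = int(float(p[_ACC_CHARGE]["value"]))
        elif name == "binaryDataArray":
            p = _cv_params(scan)
            if _ACC_MZ_ARRAY in p:
                mz_arr = _decode_array(scan)
            elif _ACC_INT_ARRAY in p:
                intensity_arr = _decode_array(scan)
    return Spectrum(
        mz=mz_arr,
        intensity=intensity_arr,
        ms_level=ms_level,
        rt=rt,
        precursor_mz=prec_mz,
        precursor_charge=prec_z,
        id=str(elem.get("id", "")),
    )


def read_mzml(path) -> Iterator[Spectrum]:
    """Stream spectra from an mzML file.

    Yields :class:`~glycompose.ms2.Spectrum` objects with MS level,
    retention time in seconds and, for MS2, precursor m/z and charge
    (charge is ``None`` when the file does not record it). Profile-mode
    spectra trigger a warning (downstream matching expects centroids).
    Malformed XML raises ``ValueError`` with parser context.
    """
    try:
        context = etree.iterparse(str(path), events=("end",))
        for _, elem in context:
            if _local(elem.tag) == "spectrum":
                yield _parse_spectrum(elem)
                elem.clear()  # free processed subtree: constant memory
                parent = elem.getparent()
                while parent is not None and elem.getprevious() is not None:
                    del parent[0]
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed mzML file {path}: {exc}") from exc


def _b64_doubles(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *map(float, values))
    return base64.b64encode(raw).decode("ascii")


def _cv(accession: str, name: str, value: str = "", unit: str = "") -> str:
    return (
        f'<cvParam cvRef="MS" accession="{accession}" name="{escape(name)}" '
        f'value="{escape(str(value))}"{unit}/>'
    )


_SECONDS = ' unitCvRef="UO" unitAccession="UO:0000010" unitName="second"'


def write_mzml(spectra: Iterable[Spectrum], path) -> None:
    """Write spectra to a minimal, standards-conformant mzML file."""
    spectra = list(spectra)
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<cvList count="2">',
        '<cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>',
        '<cv id="UO" fullName="UNIT-ONTOLOGY" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>',
        "</cvList>",
        '<run id="run">',
        f'<spectrumList count="{len(spectra)}">',
    ]
    for i, spec in enumerate(spectra):
        sid = spec.id or f"scan={i + 1}"
        lines.append(
            f'<spectrum index="{i}" id="{escape(sid)}" defaultArrayLength="{len(spec)}">'
        )
        lines.append(_cv("MS:1000511", "ms level", spec.ms_level))
        lines.append(_cv("MS:1000127", "centroid spectrum"))
        lines.append('<scanList count="1"><scan>')
        if spec.rt is not None:
            lines.append(_cv("MS:1000016", "scan start time", spec.rt, _SECONDS))
        lines.append("</scan></scanList>")
        if spec.ms_level >= 2 and spec.precursor_mz is not None:
            lines.append(
                '<precursorList count="1"><precursor>'
                '<selectedIonList count="1"><selectedIon>'
            )
            lines.append(_cv("MS:1000744", "selected ion m/z", spec.precursor_mz))
            if spec.precursor_charge is not None:
                lines.append(_cv("MS:1000041", "charge state", spec.precursor_charge))
            lines.append("</selectedIon></selectedIonList></precursor></precursorList>")
        lines.append('<binaryDataArrayList count="2">')
        for accession, name, values in (
            ("MS:1000514", "m/z array", spec.mz),
            ("MS:1000515", "intensity array", spec.intensity),
        ):
            payload = _b64_doubles(values)
            lines.append(f'<binaryDataArray encodedLength="{len(payload)}">')
            lines.append(_cv("MS:1000523", "64-bit float"))
            lines.append(_cv("MS:1000576", "no compression"))
            lines.append(_cv(accession, name))
            lines.append(f"<binary>{payload}</binary>")
            lines.append("</binaryDataArray>")
        lines.append("</binaryDataArrayList>")
        lines.append("</spectrum>")
    lines += ["</spectrumList>", "</run>", "</mzML>"]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines))
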