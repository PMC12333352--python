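"""MS2 extraction and precursor-constrained fragment annotation."""

import numpy as np
import pandas as pd
import pytest

from glycompose import (
    Composition,
    FragmentParams,
    Spectrum,
    annotate_ms2,
    extract_ms2,
    fragment_space,
    make_ms2_fixture,
    mz,
    parse_adduct,
    parse_name,
    sub_compositions,
)
from glycompose.ms2 import BARE_SULFATE_MZ


def _spec(premz, z=-2, rt=None, peaks=((100.0, 1.0),)):
    arr = np.array(peaks)
    return Spectrum(arr[:, 0], arr[:, 1], ms_level=2, rt=rt,
                    precursor_mz=premz, precursor_charge=z)


@pytest.fixture
def annotations():
    return pd.DataFrame(
        {
            "mz": [394.049, 243.018],
            "rt": [780.0, 400.0],
            "composition": ["Hex4 AnhydroBridge2 Sulfate2", "DeoxyHex1 Sulfate1"],
            "adduct": ["[M-2H]2-", "[M-H]-"],
            "charge": [-2, -1],
        }
    )


def test_extract_retains_annotated_precursors(annotations):
    keep = _spec(394.050)
    drop = _spec(1000.0)
    out = extract_ms2([keep, drop], annotations, mz_tol=0.01)
    assert len(out) == 1
    spec, hits = out[0]
    assert spec is keep
    assert list(hits.composition) == ["Hex4 AnhydroBridge2 Sulfate2"]


def test_extract_rt_window(annotations):
    near = _spec(394.050, rt=785.0)
    far = _spec(394.050, rt=400.0)
    out = extract_ms2([near, far], annotations, mz_tol=0.01, rt_window=30.0)
    assert [s.rt for s, _ in out] == [785.0]


def test_extract_carries_multiple_annotations(annotations):
    double = pd.concat([annotations, annotations.iloc[[0]].assign(
        composition="Hex4 Dehydrated2 Sulfate2")], ignore_index=True)
    out = extract_ms2([_spec(394.050)], double, mz_tol=0.01)
    _, hits = out[0]
    assert len(hits) == 2


def test_extract_warns_on_no_ms2(annotations, caplog):
    ms1 = Spectrum(np.array([100.0]), np.array([1.0]), ms_level=1)
    with caplog.at_level("WARNING"):
        out = extract_ms2([ms1], annotations)
    assert out == []
    assert "no MS2" in caplog.text


def test_sub_compositions_are_component_wise_subsets(fucoidan_fragment):
    prec = parse_name("DeoxyHex2 Sulfate3")
    for sub in sub_compositions(prec):
        assert 1 <= sub.dp <= prec.dp
        assert sub.n_hex <= prec.n_hex
        assert all(sub.count(k) <= prec.count(k) for k in prec.mods)


def test_fragment_space_includes_chain_shortened_ion():
    prec = parse_name("DeoxyHex2 Sulfate3")
    space = list(fragment_space(prec, -2))
    names = {(r.composition.name, r.adduct.name) for r in space}
    assert ("DeoxyHex1 Sulfate1", "[M-H]-") in names
    theo = mz(parse_name("DeoxyHex1 Sulfate1"), parse_adduct("[M-H]-"))
    got = next(r.mz for r in space
               if (r.composition.name, r.adduct.name) == ("DeoxyHex1 Sulfate1", "[M-H]-"))
    assert got == pytest.approx(theo, abs=1e-9)


def test_fragment_space_respects_precursor_contents():
    space = list(fragment_space(parse_name("Hex2"), -1))
    assert all(r.composition.count("sulfate") == 0 for r in space)
    assert all(abs(r.charge) == 1 for r in space)


def test_fragment_space_closure_with_dehydration_allowance():
    prec = parse_name("DeoxyHex2 Sulfate2")
    params = FragmentParams(extra_dehydrations=2)
    for r in fragment_space(prec, -2, params):
        frag = r.composition
        assert frag.count("dehydrated") <= prec.count("dehydrated") + 2
        for k in frag.mods:
            if k != "dehydrated":
                assert frag.count(k) <= prec.count(k)


def test_fragment_space_size_matches_combinatorial_bound():
    # Hex2 Sulfate1, charge -1: sub-compositions (hex 1..2) x (sulfate 0..1)
    # x dehydration allowance 0..2 x one adduct x one charge
    space = list(fragment_space(parse_name("Hex2 Sulfate1"), -1,
                                FragmentParams(extra_dehydrations=2)))
    assert len(space) == 2 * 2 * 3


def test_bare_sulfate_fragment_option():
    prec = parse_name("DeoxyHex1 Sulfate1")
    base = {r.adduct.name for r in fragment_space(prec, -1)}
    assert "HSO4-" not in base
    with_hso4 = list(fragment_space(prec, -1, FragmentParams(bare_sulfate=True)))
    hso4 = [r for r in with_hso4 if r.adduct.name == "HSO4-"]
    assert len(hso4) == 1
    assert hso4[0].mz == pytest.approx(96.9601, abs=1e-4)
    assert BARE_SULFATE_MZ == pytest.approx(96.9601, abs=1e-4)


def test_annotate_ms2_roundtrip_recovers_all_planted_fragments():
    prec = parse_name("DeoxyHex2 Sulfate3")
    premz = mz(prec, parse_adduct("[M-2H]2-"))
    spectrum, truth = make_ms2_fixture(prec, -2, n_fragments=8, ppm_jitter=1.0,
                                       seed=5, precursor_mz=premz)
    pa = pd.DataFrame([{"mz": premz, "composition": prec.name,
                        "adduct": "[M-2H]2-", "charge": -2}])
    out = annotate_ms2(spectrum, pa, tol_ppm=3.0)
    recovered = set(zip(out.composition, out.adduct))
    assert set(zip(truth.composition, truth.adduct)) <= recovered
    assert (out.precursor_composition == prec.name).all()


def test_annotate_ms2_intensity_floor():
    prec = parse_name("Hex2 Sulfate1")
    premz = mz(prec, parse_adduct("[M-H]-"))
    frag = mz(parse_name("Hex1 Sulfate1"), parse_adduct("[M-H]-"))
    spectrum = Spectrum(np.array([frag, 150.0]), np.array([1000.0, 10.0]),
                        ms_level=2, precursor_mz=premz, precursor_charge=-1)
    pa = pd.DataFrame([{"mz": premz, "composition": prec.name,
                        "adduct": "[M-H]-", "charge": -1}])
    out = annotate_ms2(spectrum, pa, tol_ppm=3.0, intensity_floor=0.8)
    assert set(out["mz"].round(3)) == {round(frag, 3)}
    assert out.intensity.iloc[0] == pytest.approx(1.0)


def test_union_of_precursor_annotations():
    premz = 394.05
    spectrum = _spec(premz, z=-2, peaks=((100.0, 1.0),))
    pa = pd.DataFrame(
        [
            {"mz": premz, "composition": "Hex4 AnhydroBridge2 Sulfate2",
             "adduct": "[M-2H]2-", "charge": -2},
            {"mz": premz, "composition": "Hex4 Dehydrated2 Sulfate2",
             "adduct": "[M-2H]2-", "charge": -2},
        ]
    )
    # plant one fragment from each precursor space
    f1 = mz(parse_name("Hex1 AnhydroBridge1 Sulfate1"), parse_adduct("[M-H]-"))
    f2 = mz(parse_name("Hex2 Dehydrated1 Sulfate1"), parse_adduct("[M-H]-"))
    spectrum = Spectrum(np.array([f1, f2]), np.array([1.0, 1.0]), ms_level=2,
                        precursor_mz=premz, precursor_charge=-2)
    out = annotate_ms2(spectrum, pa, tol_ppm=3.0)
    assert set(out.precursor_composition) == {
        "Hex4 AnhydroBridge2 Sulfate2", "Hex4 Dehydrated2 Sulfate2",
    }
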