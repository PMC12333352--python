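# glycompose

De novo annotation of glycan compositions in mass spectrometry data.

Glycan annotation usually leans on experimental structure databases, which
cover only a sliver of the compositions that glycans — sulfated algal
polysaccharides, mammalian N-glycans, plant cell-wall oligomers — can
actually take. `glycompose` goes the other way: it **enumerates every
composition** a user-constrained space allows, filters it down to
chemically plausible candidates, predicts the ionic species those
compositions form under ESI or MALDI, and matches experimental peaks
against the resulting theoretical m/z table. It is aimed at analytical
chemists and glycoscientists working with LC-MS, direct-infusion or
MALDI-imaging data on oligosaccharides that databases do not cover.

## The model

A *composition* is a count vector over monomers and modifications: hexose
(Hex) and pentose (Pent) are the base monomers, and every functional
group — sulfate, phosphate, N-acetyl, O-acetyl, O-methyl, amino,
carboxylic acid, deoxy, anhydro bridge, sialic acid (NeuAc) — is a mass
delta not tied to a particular monomer. For a degree-of-polymerization
(DP) range [d, D], m enabled modification types and c monomer types, the
unfiltered space has exactly

    N = Σ_{i=d}^{D} (i + 1)^(m + c − 1)

compositions, which the enumerator reproduces one-for-one. Candidates are
then filtered by (i) the average number of modifications per monomer
(≤ 3) and (ii) a rule set stating which modifications can sit on which
monomer kinds, at what per-monomer capacity, and which pairs cannot share
a monomer — decided exactly by a feasibility search over per-monomer
modification profiles. Surviving compositions are expanded to adducts
([M−H]⁻, [M−2H]²⁻, [M+Cl]⁻, [M+Na]⁺, Na/K exchange series
[M−(k+z)H+kNa]^z−, …) with electron-correct monoisotopic m/z; peaks match
when |(m/z_obs − m/z_theo)/m/z_theo| · 10⁶ ≤ tolerance. MS2 spectra whose
precursors carry MS1 annotations are annotated against a fragment space
of precursor sub-compositions (chain shortening, sulfate and water
losses, charge reduction).

A companion calculator counts *linear structural isomers* for a chain of
d monomers with H hexoses, combining anomeric configurations (2^d), ring
forms (2^d), ring-carbon stereocentres (2^(3d+H)), monomer arrangements
(C(d,H)) and glycosidic linkage positions (4 per hexose acceptor, 3 per
pentose, with a terminal correction), in exact big-integer arithmetic.

## Worked example

Sulfated fucose oligomers (deoxyhexose + sulfate, double sulfation
allowed) in negative-mode ESI:

```sh
$ glycompose predict --dp 1:2 --monomers hex --mods "deoxy,sulfate" \
      --double-sulfate --polarity negative --ionization esi --max-charge 2
composition	dp	neutral_mass	adduct	charge	mz
Hex1	1	180.063388	[M-H]-	-1	179.056112
Hex1	1	180.063388	[M+Cl]-	-1	215.032789
Hex1 Sulfate1	1	260.020203	[M-H]-	-1	259.012927
Hex1 Sulfate1	1	260.020203	[M-2H+Na]-	-1	280.994871
...
```

Each row is one theoretical ion: `Hex1 Sulfate1` is a monosulfated
hexose (neutral monoisotopic mass 260.020203 Da), observed deprotonated
at m/z 259.012927 or as the sodium-exchanged species [M−2H+Na]⁻ at
280.994871 (exchange is only generated for compositions with anionic
groups). A monosulfated deoxyhexose — monosulfated fucose in a fucoidan
digest — appears at m/z 243.018012 as [M−H]⁻.

Annotating a peak table against that space:

```sh
$ glycompose annotate --peaks peaks.tsv --ppm 3 --dp 1:2 --monomers hex \
      --mods "deoxy,sulfate" --double-sulfate --collapse
mz	intensity	annotations	n_annotations
234.012257	30145.101043	DeoxyHex2 Sulfate2: [M-2H]2-	1
...
```

`n_annotations` counts how many (composition, adduct) pairs fall within
the ppm window of the peak; ambiguous peaks carry every candidate.

Counting linear hexasaccharide isomers (hexose and/or pentose monomers):

```sh
$ glycompose isomers --dp 6
518781583491072
```

The library API mirrors the CLI (`PredictParams`, `prediction_table`,
`annotate`, `fragment_space`, `isomer_count_total`, …); see the module
docstrings and `docs/methods.md`.

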