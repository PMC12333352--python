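# Methods

This note records the models, conventions and numerical choices behind
`glycompose`, and what its synthetic tests do and do not demonstrate.

## Composition model and mass arithmetic

A composition is the count vector (n_hex, n_pent, counts per modification,
optional label). DP = n_hex + n_pent; sialic acid (NeuAc), although
displayed as a monomer in names, does not increase DP (configurable
nowhere — it is a fixed convention of this package; the naming layer and
the density filter both treat NeuAc as monomer-like).

Neutral monoisotopic mass is residue arithmetic:

    M = n_hex·M(C6H10O5) + n_pent·M(C5H8O4) + Σ mods·Δ + Δ_label + M(H2O)

with every residue and delta mass derived from a single monoisotopic
atomic-mass table (IUPAC values; proton 1.00727646 Da, electron
0.00054858 Da). The modification deltas are elemental-formula
differences: deoxy −O (−15.994915), sulfate +SO3 (+79.956815), phosphate
+HPO3 (+79.966330), N-acetyl +C2H3N (+41.026549, OH→NHAc), O-acetyl
+C2H2O (+42.010565), O-methyl +CH2 (+14.015650), amino +NH−O (−0.984016),
carboxylic acid +O−2H (+13.979265, C6 oxidation), NeuAc +C11H17NO8
(+291.095417), and anhydro-bridge / dehydrated / unsaturated each −H2O
(−18.010565) — three distinct names for distinct structural features with
one mass. The amino-pentyl linker is +C5H11N (+85.089149, anomeric
OH→O-pentylamine); custom labels take a user formula.

Naming approximates IUPAC condensed style: deoxy units display pairwise
with hexoses as `DeoxyHexK`, monomer terms (Hex, Pent, DeoxyHex) first,
remaining components alphabetically, e.g. `Hex7 N-Acetyl3 NeuAc1
O-Acetyl1 Sulfate3`. Names round-trip through the parser exactly.

## Enumeration and the closed form

For DP i, the hexose count ranges over 0..i when both monomer kinds are
enabled and each enabled modification count independently ranges 0..i
(assumption: one unit of each modification per monomer at most, all
modifications simultaneously possible — relaxed later by the rule
filter). This gives exactly N = Σ (i+1)^(m+c−1) rows, which the test
suite verifies by exhaustive enumeration for all d ≤ D ≤ 8, m ≤ 3.

Two deliberate departures from the closed form:

- **Double sulfation** extends only the sulfate range to 0..2i
  (disulfated fucose is a real fucoidan motif), intentionally breaking
  the equality.
- **Deoxy** is capped at the hexose count at build time (a deoxygenated
  pentose is not representable here), so spaces that enable deoxy are
  slightly smaller than the closed form; count-equality checks use
  non-deoxy modification sets.

Enumeration order is DP ascending, hexose count descending, modification
counts in nested alphabetical loops — deterministic output for diffing.
The enumerator is a generator; the full pipeline (density filter → rule
filter → adduct expansion) is generator-chained, so memory is flat in
row count. The suite consumes the complete DP 1–12, four-modification
space (1,002,000 rows) and spot-checks laziness of the DP 1–22 space;
those sizes were chosen as a compact exercise of the same streaming
discipline that carries the DP 1–22 space.

## Density and rule filtering

Density = (Σ density-counting modification units) / (DP + NeuAc count),
kept when ≤ max_avg (≤ 3). Deoxy and NeuAc units are excluded from the
numerator and NeuAc enters the denominator, matching their monomer-like
naming; this convention is this package's own choice where conventions
differ between tools.

Rule feasibility asks: can the modification units (including deoxy,
excluding NeuAc, which occupies no ring) be assigned to monomer
instances so that each unit lands on an allowed monomer kind, no monomer
exceeds a per-kind capacity or the per-monomer total cap (default 3),
and no excluded pair shares a monomer? Monomers of a kind are
interchangeable, so the decision is solved exactly over per-monomer
*profiles* (valid single-monomer modification multisets, enumerated once
per rule set and cached) with a count-cover search — no heuristics, and
the tests verify exact agreement with a brute-force unit-placement
oracle over randomized rule sets.

The default rule set: sulfate, phosphate, O-methyl, O-acetyl, N-acetyl,
amino on either monomer kind; anhydro-bridge, carboxylic acid and deoxy
hexose-only; capacity 1 per kind (sulfate 2 when double sulfation is
on); carboxylic acid excluded with anhydro-bridge and with deoxy (all
modify C6); N-acetyl excluded with amino (same amino position). Every
entry is overridable via a YAML file (`glycompose predict --rules`).
N-/O-glycan presets ship as editable YAML element-limit files
(e.g. N-glycan: hex 3–12, N-acetyl 2–8, pentose 0) and only tighten the
default rules; their numeric ranges are package defaults in the spirit
of classic compositional annotation tools and should be adjusted to the
glycome at hand.

## Ionization

Adduct deltas are parsed from names (`[M-2H+Na]-`, `[M-4H+5Na]+`, …) and
computed as the sum of neutral atoms gained/lost minus charge · m_e —
identical to proton bookkeeping at ±1.00727646 Da per charge,
+21.981944 Da per H→Na and +37.955882 Da per H→K exchange. Cation
exchange replaces acidic protons, so an adduct that exchanges k protons
requires ≥ k anionic groups (sulfate + phosphate + carboxylate + NeuAc);
compositions lacking them skip the adduct silently (logged). Defaults:
ESI negative {[M−zH]z−, [M+Cl]−, Na/K exchange ladders}, ESI positive
{[M+H]+, [M+Na]+, [M+K]+, [M+NH4]+, exchange ladders}, MALDI the singly
charged subset. ESI charge is capped at min(max_charge, DP), default
max_charge 3; MALDI at 1. These default adduct lists are this package's
own choices and are fully overridable (`--adducts`).

## Annotation

MS1 matching uses a sorted theoretical m/z index with binary search on
the window bounds obs/(1+tol) ≤ theo ≤ obs/(1−tol); the reported ppm
error is signed, (observed − theoretical)/theoretical · 10⁶. Default
tolerance 5 ppm, with presets reflecting common instrument setups
(Orbitrap 1.5–3 ppm, QTOF 15 ppm). Unmatched peaks are kept with empty
annotation fields by default. One peak may carry several annotations;
`collapse` concatenates them alphabetically with an `n_annotations`
count. A local TSV database can be left-joined by canonical composition
name; duplicate keys concatenate with a warning.

MS2: spectra are retained when the precursor m/z lies within an absolute
tolerance (default 0.01 Da, optional retention-time window) of an
annotated MS1 peak. The fragment space of a precursor is all
sub-compositions (every count 0..precursor count, DP ≥ 1, label retained
or lost) × 0..2 extra water losses (glycosidic B/Y cleavage plus one
dehydration; configurable) × charges 1..|z_precursor| in the precursor
polarity × deprotonated/protonated (optionally cation-exchanged)
adducts. The diagnostic bisulfate anion HSO4⁻ (m/z 96.9601) is available
behind an option for sulfated precursors. Multiple precursor
annotations union their fragment spaces and each output row records its
precursor identity. Intensity normalization to max 1 with an optional
floor is applied before matching when requested. This sub-composition
grammar is this package's own fragment model; it deliberately excludes
cross-ring (A/X) fragments.

## Isomer counting

The linear-isomer count factorises as I(d,H) = 2^d (anomeric) ·
2^(3d+H) (ring-carbon stereocentres: 4 per hexose, 3 per pentose) ·
C(d,H) (arrangements) · 4^H·3^(d−H)·((d−H)/(3d) + H/(4d)) (linkage
positions with the terminal monomer, which accepts no incoming linkage,
averaged over arrangements) · 2^d (ring forms). The rational bracket
always cancels: C(d,H)(d−H)/d = C(d−1,H) and C(d,H)H/d = C(d−1,H−1)
count arrangements by terminal monomer kind. Arithmetic is exact
`fractions`/int — results pass 64 bits near DP 8 — and floating point is
never used in this module. The factorisation is validated against
explicit per-factor enumeration at d ≤ 2 and the hexose+pentose
hexasaccharide total 518,781,583,491,072. Modifications are not counted:
their placement constraints do not factorise.

## Synthetic fixtures

`make_ms1_fixture` plants peaks at theoretical m/z × (1 + ε) with ε from
a normal (σ = ppm_jitter) truncated at ±2.5σ — truncation makes a
3σ matching tolerance recover every planted peak deterministically —
plus log-uniform intensities and decoy peaks resampled until ≥ 3σ (with
a 0.5 ppm floor, covering the σ = 0 case) away in ppm from every planted
theoretical m/z, so decoys can never be annotated at 3σ tolerance.
`make_ms2_fixture` samples distinct fragment ions from the precursor's
fragment space. Fixtures emulate centroided peak lists only: no isotope
envelopes, chromatographic peak shape, baseline noise, profile spectra
or intensity-dependent mass error. Passing round-trip tests therefore
demonstrates the correctness of the matching and bookkeeping machinery,
not annotation specificity on real, dense spectra — on real data,
annotation multiplicity and false matches grow with the size of the
predicted ion space, and orthogonal evidence (MS2, retention time,
isotopes) remains necessary.

## Numerical conventions and edge cases

- Masses and m/z are printed at 6 decimals, ppm errors at 2; tables are
  UTF-8, '\n', '.' decimal separator.
- The density filter compares with a 1e-9 epsilon so exact boundary
  ratios (e.g. 2 sulfates on 2 monomers at max_avg 1) are kept.
- DP 0 compositions are rejected except as labelled species; deoxy >
  hexose count is rejected at construction.
- mzML reading is a streaming parser over the standard CV params
  (32/64-bit float arrays, none/zlib compression); profile-mode spectra
  produce a warning, MS2 scans without a charge state record charge as
  unknown and downstream code falls back to the annotation's charge.
- Determinism: identical parameters, inputs and seed give byte-identical
  output tables.

## Known limitations

- Composition-level only: no linkage, branching or positional isomer
  resolution, and no SNFG rendering.
- No isotope-pattern prediction or peak-picking; inputs must be
  centroided and deisotoped upstream.
- The default rule set encodes broadly applicable monosaccharide
  chemistry but cannot know organism-specific constraints; users should
  tighten it per system.
- Isomer counts cover linear chains only and ignore modifications.
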