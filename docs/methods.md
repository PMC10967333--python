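# Methods

## Scope and model

`fcglycoscope` implements the computational arm of an Fc N-glycosylation
characterisation workflow for an IgG1 antibody: starting from tandem-MS runs
of a Glu-C + trypsin digest, it (i) flags glycopeptide-derived HCD spectra by
their oxonium-ion content, (ii) assigns a peptide + glycan composition to
each flagged spectrum with fragment-level site localisation, (iii) reads the
relative abundance of each glycoform from MS1 precursor peak heights, and
(iv) quantifies what fraction of peptide copies carry any glycan at the
sequon, using the ¹⁸O/PNGase-F deamidation chemistry. A seeded generator
produces synthetic runs with ground truth so every estimator can be
validated by parameter recovery.

The biological target is the conserved heavy-chain CH2 sequon (Asn297 in the
tryptic context `²⁹³EEQYNSTYR³⁰¹`), but nothing is hard-wired to it: any
protein FASTA, sequon and composition library can be supplied.

## Mass conventions

All masses are monoisotopic. Monosaccharides carry dehydrated residue masses
(HexNAc 203.07937, Hex 162.05282, Fuc 146.05791, NeuAc 291.09542 Da) and
glycan attachment to Asn adds no water, so a glycopeptide's neutral mass is
exactly `peptide + glycan`. Protonated species use m/z = (M + z·1.0072765)/z;
the electron mass is not subtracted separately (the error, ~0.5 ppm at z = 1,
is far below every tolerance used). Under these conventions the doubly
protonated `EEQYNSTYR + HexNAc₄Hex₃` ion computes to m/z 1244.4976, matching
the reference annotation to four decimals. The seven diagnostic oxonium ions
are carried at their conventional printed m/z values in the triage panel;
first-principles sums agree with them within 0.001 Da, well inside the
15 ppm matching window. The mass table ships as a versioned JSON resource
and can be overridden.

¹⁸O deglycosylation shifts the peptide by deamidation (+0.98402) plus the
¹⁸O−¹⁶O difference (+2.00425) = +2.98826 Da.

## Digestion

The combined Glu-C + trypsin digest pools both enzymes' cleavage sites into
one set; a peptide's missed-cleavage count is the number of internal pooled
sites and is bounded by the budget (default 2). Trypsin cuts after K/R but
not before proline; Glu-C cuts after E only, including E–P (common search-
engine defaults; both proline flags are configurable). Sequons are N-X-S/T
with X ≠ P, judged on the protein so that a sequon whose S/T falls in the
next peptide is still annotated.

## Triage

The instrument's acquisition trigger — at least two of the oxonium panel
ions present within 15 ppm — is reimplemented as an offline filter with
identical logic. The panel carries all seven reference ions; `min_hits`
stays 2. No intensity floor is applied by default (a relative floor is
available). The rule is monotone: adding peaks or widening the tolerance can
only add matches.

## Scoring and localisation

Candidates are all (peptide-form, site, composition) triples whose
theoretical m/z lies within the MS1 tolerance (10 ppm) of the precursor;
peptides without sequons enter only as bare peptides. Variable
modifications: Met oxidation (≤2) and protein N-terminal acetylation;
deamidation is handled only in the occupancy workflow. Theoretical fragments
are the bare b/y ladder, the Y series (peptide plus leading glycan remnants
along a core-out trimming path — chitobiose HexNAc, core Hex up to 3, then
remaining antennae, Fuc, NeuAc — truncated at 8 remnants by default),
site-spanning b/y ions retaining HexNAc₁/HexNAc₂, and the oxonium B ions.

The score (0–100) is a transparent counting heuristic:

    score = matched_by/(2(n−1))·50 + min(matched_Y, 5)·8 + 10·[≥2 oxonium]
            − 15·[precursor off by more than the MS1 tolerance]

floored at 0. The precursor term is needed to rank a wrong glycan below the
right one when both are scored against the same spectrum outside a search
(the truncated Y ladders of two related compositions share all low
remnants); inside a search it never fires because candidates are
precursor-filtered. Ties break by |precursor ppm|, then fewer glycan
residues, then composition and sequence — fully deterministic. A match is
"site-localised" when at least one glycan-remnant b/y ion spanning the site
is observed (the b₅/y₅ + HexNAc pattern). No FDR is estimated; the report
carries the per-fragment evidence a reviewer needs instead.

## Quantification

*Glycoform profile.* Per identified composition, the supporting intensity is
the apex over its GPSMs of the MS1 monoisotopic precursor height summed over
charge states {2, 3}, searched in the MS1 scans within ±30 s of the MS2
trigger; fractions are normalised over the observed compositions. Heights,
not areas, are used, and no cross-run normalisation is attempted.

*Site occupancy.* Per charge state, the unlabeled (Asn) and labeled
(+2.98826 Da) monoisotopic heights are summed over MS1 scans. At orbitrap
resolving powers the labeled monoisotopic peak co-centroids with the M+3
isotopologue of the unlabeled envelope (separation 0.0218/z m/z versus a
2×FWHM centroid-separation limit), so the labeled height is corrected by
subtracting `unlabeled × (M+3/M)` predicted from the peptide's isotope
envelope (correction configurable off; demonstrating its effect requires a
matching window wide enough to include the merged centroid, ~25 ppm at
charge 2–3, because at occupancy ≈ 0 the merged peak sits at the M+3
position itself). Occupancy is the corrected labeled fraction aggregated
over charge states by intensity weighting. The 97% labeling purity is
modeled in the generator but deliberately ignored by the estimator; the
induced bias, −θ(1−p)(1−θ)/(1−θ(1−p)), peaks at ~0.8 percentage points near
θ = 0.5 and is inside the ±2-point validation band. Natural deamidation
(+0.98402, ¹⁶O) is excluded from numerator and denominator and flagged when
its peak exceeds 5% of the unlabeled height.

*Isotope envelopes* are aggregated isotopologue distributions computed by
convolving per-element neutron-shift vectors (C, H, N, O, S; binary-power
convolution, truncated), normalised to the base peak; elemental compositions
come from the peptide sequence plus modification and monosaccharide
formulas.

## Synthetic-run generator

The generator emulates the study's acquisition, not chromatography: no peak
shapes, co-isolation or vendor artifacts. Defaults (all in `SynthConfig`):

| parameter | default | why |
|---|---|---|
| resolving power | 120,000 @ m/z 200, ∝ 1/√(m/z) | acquisition setting of the reference runs |
| centroid separation limit | 2 × FWHM | folds unresolved neighbours (the M+3/¹⁸O overlap) into one weighted centroid |
| charge states | {2, 3}, weights 0.7/0.3 | typical tryptic glycopeptide charges |
| m/z jitter | σ = 2 ppm | comfortably inside the 10/20 ppm tolerances |
| peak-height noise | log-normal, CV 5% | MS1 height repeatability |
| noise peaks | 40 (MS1) / 60 (MS2) per scan, exponential at 1% of base | background chemical noise |
| MS2 repeats per glycoform | 3 | repeated sampling across elution |
| decoy events | 2 bare-peptide MS1+MS2 pairs | triage false-positive control |
| ¹⁸O water purity | 0.97 | labeling protocol |
| deglyco MS1 scans | 8 | scan-averaged height estimate |

Platform presets pin the study conditions: `hca-n` (tobacco) has 13
glycoforms dominated by G0 with oligomannose/hybrid/complex all present,
exactly 1% total fucosylation, occupancy 0.491; `hca-mrna` (vaginal-cell
mRNA) has 11 fairly evenly distributed glycoforms led by G0F/G1F/G2F,
including G2S1F and monoHexNAc, occupancy 0.960. The compositions named in
the study text anchor each preset; the filler glycoforms and all numeric
weights are package constants chosen once, documented here, and not
literature claims. The heavy/light-chain sequences are unpublished, so the
FASTA fixtures are explicitly synthetic scaffolds carrying only what the
pipeline exercises (the CH2 context at 293–301 and a second sequon at N71).

Because the generator emits the same theoretical fragment set the scorer
predicts, noiseless identification is perfect by construction; what the
tests demonstrate on top of that is robustness to jitter/noise, correct
triage gating, quantitative recovery of profile weights (±0.05) and
occupancy (mean |error| ≤ 2 points over seeds), and determinism
(byte-identical MGF per seed). They do not demonstrate robustness to
chimeric spectra, isomer separation, or retention-time effects — real-data
concerns outside this model.

## Numerical and format choices

MGF is the interchange format; because occupancy runs are MS1-only, blocks
carry an `MSLEVEL` header and MS1 blocks legitimately lack PEPMASS (an MS2
block without PEPMASS is an error naming the block). m/z is serialised at
5 decimals and intensity at 6 significant digits — an order below the
round-trip contract (1e-4 m/z, 0.1% intensity). mzML support is a read-only
centroided subset (64/32-bit float, zlib or none) implemented directly over
lxml; anything else raises an explicit unsupported-feature error.
Peak-match ties break by intensity, then smaller |Δppm|. Glycan
classification is a counts-only heuristic (HexNAc2/Hex≥5 oligomannose;
HexNAc3/Hex≥5/no NeuAc hybrid; other HexNAc≥3 complex; rest "other"
including monoHexNAc and paucimannose) — composition data cannot see
topology, and reports treat the class as derived, with a per-library
override column.

## Known limitations

- Composition-level only: no linkage, no isomer separation, no xylose-type
  plant glycans (the production platform modeled here has them knocked out).
- O-glycopeptides, ETD/EThcD and chimeric spectra are out of scope.
- The score has no FDR calibration; it is a manual-review aid validated on
  synthetic data.
- Occupancy assumes equal ionisation efficiency of the Asn and Asp(¹⁸O)
  forms (they co-elute closely and differ by 3 Da; any differential response
  would bias the ratio).
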