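# fcglycoscope

Glycoproteomic profiling of IgG Fc N-glycans from tandem mass spectrometry
runs: in-silico Glu-C + trypsin digestion, oxonium-ion triage of HCD
spectra, glycopeptide-spectrum matching (GPSM) with fragment-level site
localisation, MS1-based glycoform quantification, and ¹⁸O-PNGase-F
glycosylation-site occupancy — plus a seeded synthetic-run generator with
per-scan ground truth for validating every estimator.

The package is aimed at analysts characterising antibody N-glycosylation —
e.g. comparing the Fc glycan profile of the same IgG1 produced on different
expression platforms, where site occupancy, glycan classes and glycoform
distributions all shift.

## The core quantities

For a tryptic sequon peptide (the conserved CH2 context
`²⁹³EEQYNSTYR³⁰¹`, site Asn297) carrying glycan composition
HexNAc_a Hex_b Fuc_c NeuAc_d:

- **precursor m/z** (charge z): `(M_pep + M_glycan + z·m_H⁺)/z` with
  dehydrated monosaccharide residues and anhydrous attachment —
  `EEQYNSTYR + HexNAc₄Hex₃` at z = 2 gives m/z 1244.4976;
- **triage rule**: a spectrum is glycopeptide-derived if ≥2 of the oxonium
  panel (m/z 204.0867, 138.0545, 366.1396, 168.0653, 186.0760, 292.1031,
  274.0927) match within 15 ppm;
- **GPSM score** (0–100): `matched_by/(2(n−1))·50 + min(matched_Y,5)·8 +
  10·[≥2 oxonium] − 15·[precursor mismatch]`, with site localisation from
  glycan-remnant b/y ions (b₅/y₅ + HexNAc);
- **glycoform fraction**: MS1 monoisotopic precursor height (apex near the
  MS2 trigger, summed over charges), normalised over observed compositions;
- **site occupancy**: after PNGase F in H₂¹⁸O converts occupied Asn to
  Asp(¹⁸O) (+2.98826 Da),
  `occupancy = L_corr / (L_corr + U)` where `L_corr` subtracts the
  unlabeled envelope's M+3 isotopologue that co-centroids with the labeled
  monoisotopic peak.

## Worked example

```bash
fcglycoscope simulate --preset hca-mrna --seed 7 --out run.mgf \
    --truth truth.tsv --fasta proteins.fasta
fcglycoscope simulate --preset hca-mrna --seed 7 --deglyco --out deglyco.mgf
fcglycoscope pipeline --glyco run.mgf --fasta proteins.fasta \
    --deglyco deglyco.mgf --out-dir out/
```

prints

```
wrote run.mgf: 70 scans, 11 glycoforms (hca-mrna)
wrote deglyco.mgf: 8 MS1 scans, true occupancy 0.960
out/: 33 GPSMs, 11 glycoforms, occupancy 95.9%
```

i.e. of 35 MS2 spectra, 33 pass oxonium triage (the 2 bare-peptide decoys
are rejected), each is assigned its generating glycopeptide, the profile in
`out/profile.tsv` recovers all 11 preset compositions with fractions within
±0.05 of the generating weights, and the ¹⁸O estimator recovers the preset
occupancy of 96.0% to within a fraction of a percentage point. The same
steps are available as library calls (`fcglycoscope.search`,
`fcglycoscope.glycoform_profile`, `fcglycoscope.occupancy_18O`, ...).

The `analysis/` directory holds the numbered study drivers
(`01_simulate_runs.py` … `04_site_occupancy.py`) that simulate both platform
presets (tobacco `hca-n`: 13 glycoforms, G0-dominant, occupancy 49.1%;
vaginal-cell mRNA `hca-mrna`: 11 glycoforms, G0F/G1F/G2F-led, occupancy
96.0%), run triage/search/profiling/occupancy, and write their tables under
`results/`.

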