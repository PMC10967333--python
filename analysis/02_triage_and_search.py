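#!/usr/bin/env python
"""Oxonium triage and glycopeptide-spectrum matching of the simulated runs.

Reads the MGF runs written by 01_simulate_runs.py, applies the two-of-panel
oxonium filter, searches the triaged spectra against the synthetic proteins
and the packaged glycan library, and compares every assignment with the
generator's ground truth. Writes triage and GPSM tables under results/.
"""

from pathlib import Path

import pandas as pd

from fcglycoscope.digestion import read_fasta
from fcglycoscope.glycans import default_library
from fcglycoscope.gpsm import SearchConfig, search
from fcglycoscope.report import gpsm_table, triage_table
from fcglycoscope.spectra import read_mgf
from fcglycoscope.synth import PRESETS

ROOT = Path(__file__).resolve().parents[1]
RUNS = ROOT / "scratch" / "runs"
RESULTS = ROOT / "results"


def main() -> None:
    proteins = read_fasta(RUNS / "synthetic_hca.fasta")
    library = default_library()
    for name in PRESETS:
        run = read_mgf(RUNS / f"{name}_glyco.mgf")
        truth = pd.read_csv(RESULTS / f"{name}_truth.tsv", sep="\t")
        tri = triage_table(run)
        tri.to_csv(RESULTS / f"{name}_triage.tsv", sep="\t", index=False)
        gpsms = search(run, proteins, library, SearchConfig())
        gpsm_table(gpsms, library).to_csv(
            RESULTS / f"{name}_gpsm.tsv", sep="\t", index=False
        )
        tmap = truth.set_index("scan_id")
        glyco_truth = tmap[~tmap["is_decoy"]]
        correct = sum(
            1
            for g in gpsms
            if g.scan_id in glyco_truth.index
            and str(g.glycopeptide.glycan) == glyco_truth.loc[g.scan_id, "composition"]
        )
        print(
            f"{name}: {int(tri['is_glyco'].sum())}/{len(tri)} spectra triaged as "
            f"glyco, {len(gpsms)} GPSMs, {correct}/{len(glyco_truth)} correct "
            f"vs ground truth ({correct / len(glyco_truth):.1%})"
        )


if __name__ == "__main__":
    main()
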