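#!/usr/bin/env python
"""Simulate the platform-specific runs the downstream analyses consume.

For each expression platform (tobacco 'hca-n', vaginal-cell mRNA 'hca-mrna')
this writes a glycopeptide HCD search run and an 18O PNGase-F MS1 run
(MGF, under scratch/runs/), the per-scan ground truth (results/), and the
synthetic protein FASTA. Everything is seeded and reproducible.
"""

from pathlib import Path

from fcglycoscope.digestion import write_fasta
from fcglycoscope.spectra import write_mgf
from fcglycoscope.synth import (
    PRESETS,
    SynthConfig,
    default_proteins,
    generate_deglyco_run,
    generate_glyco_run,
)

SEED = 7
ROOT = Path(__file__).resolve().parents[1]
RUNS = ROOT / "scratch" / "runs"
RESULTS = ROOT / "results"


def main() -> None:
    RUNS.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    write_fasta(default_proteins(), RUNS / "synthetic_hca.fasta")
    for name, preset in PRESETS.items():
        cfg = SynthConfig(preset=preset, seed=SEED)
        run, truth = generate_glyco_run(cfg)
        write_mgf(run, RUNS / f"{name}_glyco.mgf")
        truth.to_csv(RESULTS / f"{name}_truth.tsv", sep="\t", index=False)
        drun, theta = generate_deglyco_run(cfg)
        write_mgf(drun, RUNS / f"{name}_deglyco.mgf")
        print(
            f"{name}: {len(run)} scans ({len(run.ms2())} MS2, "
            f"{preset.n_glycoforms} glycoforms), deglyco {len(drun)} MS1 scans, "
            f"true occupancy {theta:.1%}"
        )
    print(f"runs -> {RUNS}, ground truth -> {RESULTS}")


if __name__ == "__main__":
    main()
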