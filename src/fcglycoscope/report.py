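"""Pipeline orchestration, sequence coverage and TSV reports.

Everything downstream-facing is a TSV with a header row; every row is
traceable to scan ids. Re-running with the same inputs and config is
bit-identical (all ordering is deterministic and all randomness lives in the
seeded generator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .chem import GlycanComposition, Glycopeptide, Peptide
from .digestion import read_fasta
from .glycans import GlycanLibrary, classify, default_library, load_library
from .gpsm import GPSM, SearchConfig, search
from .quant import GlycoformProfile, OccupancyResult, glycoform_profile, occupancy_18O
from .spectra import Run, read_mgf
from .triage import is_glyco_spectrum

log = logging.getLogger("fcglycoscope")

__all__ = [
    "coverage",
    "coverage_report",
    "triage_table",
    "gpsm_table",
    "read_gpsm_table",
    "profile_table",
    "occupancy_table",
    "PipelineResult",
    "run_pipeline",
]


def coverage(intervals: list[tuple[int, int]], protein_length: int) -> float:
    """Percent of residues covered by the union of 1-based inclusive intervals."""
    if protein_length <= 0:
        raise ValueError("protein length must be positive")
    for a, b in intervals:
        if a < 1 or b > protein_length or a > b:
            raise ValueError(f"interval [{a}, {b}] outside [1, {protein_length}]")
    covered = 0
    last_end = 0
    for a, b in sorted(intervals):
        a = max(a, last_end + 1)
        if b >= a:
            covered += b - a + 1
            last_end = max(last_end, b)
    return covered / protein_length * 100.0


def coverage_report(gpsms: list[GPSM], proteins: list[tuple[str, str]]) -> pd.DataFrame:
    """Per-protein coverage from identified peptides (by GPSM protein tag)."""
    rows = []
    for desc, seq in proteins:
        peps = sorted(
            {
                (g.glycopeptide.peptide.start, g.glycopeptide.peptide.end,
                 g.glycopeptide.peptide.sequence)
                for g in gpsms
                if g.protein == desc
            }
        )
        pct = coverage([(a, b) for a, b, _s in peps], len(seq)) if peps else 0.0
        rows.append(
            {
                "protein": desc,
                "length": len(seq),
                "coverage_percent": round(pct, 2),
                "n_peptides": len(peps),
                "peptides": ";".join(s for _a, _b, s in peps),
            }
        )
    return pd.DataFrame(rows)


def triage_table(run: Run, panel=None) -> pd.DataFrame:
    from .triage import DEFAULT_PANEL

    panel = panel or DEFAULT_PANEL
    rows = []
    for spec in run.ms2():
        res = is_glyco_spectrum(spec, panel)
        rows.append(
            {
                "scan_id": spec.scan_id,
                "is_glyco": res.is_glyco,
                "matched_ions": ";".join(res.matched_labels),
            }
        )
    return pd.DataFrame(rows, columns=["scan_id", "is_glyco", "matched_ions"])


def gpsm_table(gpsms: list[GPSM], library: GlycanLibrary | None = None) -> pd.DataFrame:
    library = library or default_library()
    rows = []
    for g in gpsms:
        gp = g.glycopeptide
        comp = gp.glycan
        rows.append(
            {
                "scan_id": g.scan_id,
                "peptide": gp.peptide.sequence,
                "start": gp.peptide.start,
                "end": gp.peptide.end,
                "mods": ";".join(f"{p}:{n}" for p, n in gp.peptide.mods),
                "site": gp.site if gp.site is not None else -1,
                "protein_site": gp.protein_site if gp.protein_site is not None else -1,
                "composition": str(comp),
                "shorthand": library.shorthand_for(comp) or "",
                "glycan_class": library.class_of(comp) if not comp.is_empty else "",
                "score": round(g.score, 2),
                "precursor_mz": round(g.precursor_mz, 5) if g.precursor_mz else "",
                "precursor_charge": g.precursor_charge or "",
                "precursor_ppm": round(g.precursor_ppm, 3) if g.precursor_ppm is not None else "",
                "site_localized": g.site_localized,
                "n_matched_fragments": len(g.matched_fragments),
                "matched_ions": ";".join(f.label for f, _m, _i in g.matched_fragments),
                "protein": g.protein or "",
            }
        )
    return pd.DataFrame(rows)


def read_gpsm_table(path: str | Path) -> list[GPSM]:
    """Rehydrate minimal GPSMs (enough for profiling) from a gpsm.tsv."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for _i, row in df.iterrows():
        pep = Peptide(row["peptide"], start=int(row["start"]), end=int(row["end"]))
        site = int(row["site"])
        comp = GlycanComposition.from_string(str(row["composition"]))
        gp = Glycopeptide(pep, site if site > 0 else None, comp)
        out.append(
            GPSM(
                scan_id=str(row["scan_id"]),
                glycopeptide=gp,
                score=float(row["score"]),
                precursor_mz=float(row["precursor_mz"]) if row["precursor_mz"] != "" else None,
                precursor_charge=int(row["precursor_charge"]) if row["precursor_charge"] != "" else None,
                precursor_ppm=None,
                matched_fragments=(),
                site_localized=bool(row["site_localized"]),
                protein=str(row.get("protein", "")) or None,
            )
        )
    return out


def profile_table(profile: GlycoformProfile, library: GlycanLibrary | None = None) -> pd.DataFrame:
    library = library or default_library()
    rows = []
    for comp, frac in profile.fractions.items():
        heights = profile.intensities.get(comp, {})
        rows.append(
            {
                "protein_site": profile.site if profile.site is not None else -1,
                "composition": str(comp),
                "shorthand": library.shorthand_for(comp) or "",
                "glycan_class": library.class_of(comp),
                "fraction": round(frac, 6),
                "intensity": round(sum(heights.values()), 2),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["protein_site", "composition", "shorthand", "glycan_class", "fraction", "intensity"],
    )
    return df.sort_values("fraction", ascending=False, kind="stable").reset_index(drop=True)


def occupancy_table(result: OccupancyResult) -> pd.DataFrame:
    rows = [
        {
            "protein_site": result.site if result.site is not None else -1,
            "occupied_fraction": round(result.occupied, 6) if result.occupied is not None else "",
            "occupied_percent": round(result.occupied * 100.0, 2) if result.occupied is not None else "",
            "quantifiable": result.quantifiable,
            "deamidation_warning": result.deamidation_warning,
            "charges_used": ";".join(str(z) for z in sorted(result.raw_heights)),
        }
    ]
    return pd.DataFrame(rows)


#: flat key-value pipeline config schema (YAML); defaults mirror the
#: reference protocol: 10/20 ppm MS1/MS2, 15 ppm / 2-hit triage, 2 missed
#: cleavages.
CONFIG_SCHEMA: dict[str, type] = {
    "ms1_tol_ppm": float,
    "ms2_tol_ppm": float,
    "max_missed": int,
    "triage_tol_ppm": float,
    "triage_min_hits": int,
    "y_depth": int,
    "variable_mods": bool,
    "occupancy_peptide": str,
    "occupancy_start": int,
    "occupancy_site": int,
}


def load_config(path: str | Path) -> dict:
    """Load and validate a flat YAML pipeline config (see CONFIG_SCHEMA)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    out = {}
    for key, value in raw.items():
        if key not in CONFIG_SCHEMA:
            known = ", ".join(sorted(CONFIG_SCHEMA))
            raise ValueError(f"{path}: unknown config key {key!r}; known: {known}")
        out[key] = CONFIG_SCHEMA[key](value)
    return out


def search_config_from(options: dict) -> SearchConfig:
    """Build a SearchConfig from flat config options (unknown keys ignored)."""
    from .triage import OxoniumPanel

    kwargs = {}
    for key in ("ms1_tol_ppm", "ms2_tol_ppm", "max_missed", "y_depth", "variable_mods"):
        if key in options:
            kwargs[key] = options[key]
    panel_kwargs = {}
    if "triage_tol_ppm" in options:
        panel_kwargs["tol_ppm"] = options["triage_tol_ppm"]
    if "triage_min_hits" in options:
        panel_kwargs["min_hits"] = options["triage_min_hits"]
    if panel_kwargs:
        kwargs["panel"] = OxoniumPanel(**panel_kwargs)
    return SearchConfig(**kwargs)


@dataclass
class PipelineResult:
    triage: pd.DataFrame
    gpsms: list[GPSM]
    gpsm: pd.DataFrame
    profile: GlycoformProfile | None
    profile_df: pd.DataFrame
    occupancy: OccupancyResult | None
    coverage: pd.DataFrame
    n_warnings: int = 0


def _as_run(run) -> Run:
    return run if isinstance(run, Run) else read_mgf(run)


def _as_proteins(proteins) -> list[tuple[str, str]]:
    if isinstance(proteins, (str, Path)):
        return read_fasta(proteins)
    return list(proteins)


def _as_library(library) -> GlycanLibrary:
    if library is None:
        return default_library()
    if isinstance(library, (str, Path)):
        return load_library(library)
    return library


def run_pipeline(
    glyco_run,
    proteins,
    library=None,
    deglyco_run=None,
    occupancy_peptide: str = "EEQYNSTYR",
    occupancy_start: int = 293,
    occupancy_site: int = 5,
    out_dir: str | Path | None = None,
    config: SearchConfig = SearchConfig(),
) -> PipelineResult:
    """Triage -> search -> glycoform profile (-> occupancy when a deglyco run
    is given); optionally writes all tables to *out_dir*."""
    run = _as_run(glyco_run)
    prots = _as_proteins(proteins)
    lib = _as_library(library)

    log.info("pipeline: %d scans (%d MS2)", len(run), len(run.ms2()))
    tri = triage_table(run, config.panel)
    gpsms = search(run, prots, lib, config)
    gdf = gpsm_table(gpsms, lib)
    log.info("search: %d GPSMs from %d triaged spectra",
             len(gpsms), int(tri["is_glyco"].sum()) if len(tri) else 0)

    n_warnings = 0
    glyco_gpsms = [g for g in gpsms if g.glycopeptide.site is not None]
    if glyco_gpsms:
        prof = glycoform_profile(
            glyco_gpsms, run, tol_ppm=config.ms1_tol_ppm, constants=config.constants
        )
        n_warnings += prof.n_excluded
    else:
        prof = None
    pdf = profile_table(prof, lib) if prof is not None else pd.DataFrame(
        columns=["protein_site", "composition", "shorthand", "glycan_class", "fraction", "intensity"]
    )

    occ = None
    if deglyco_run is not None:
        drun = _as_run(deglyco_run)
        pep = Peptide(occupancy_peptide, start=occupancy_start)
        occ = occupancy_18O(
            drun, pep, site=occupancy_start + occupancy_site - 1,
            tol_ppm=config.ms1_tol_ppm, constants=config.constants,
        )
        if not occ.quantifiable:
            log.warning("occupancy: site not quantifiable (no peaks found)")
            n_warnings += 1

    cov = coverage_report(gpsms, prots)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tri.to_csv(out / "triage.tsv", sep="\t", index=False)
        gdf.to_csv(out / "gpsm.tsv", sep="\t", index=False)
        pdf.to_csv(out / "profile.tsv", sep="\t", index=False)
        if occ is not None:
            occupancy_table(occ).to_csv(out / "occupancy.tsv", sep="\t", index=False)
        cov.to_csv(out / "coverage.tsv", sep="\t", index=False)
    if n_warnings:
        log.warning("pipeline finished with %d warning(s)", n_warnings)
    return PipelineResult(tri, gpsms, gdf, prof, pdf, occ, cov, n_warnings)
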