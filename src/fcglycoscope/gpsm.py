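"""Glycopeptide-spectrum matching.

Candidates are generated by precursor mass against digested peptides crossed
with a glycan composition library; theoretical fragments cover the peptide
b/y ladder, the Y series (peptide + leading glycan remnants along a core-out
trimming path), glycan-remnant b/y ions spanning the site (the localisation
evidence: e.g. b5+HexNAc, y5+HexNAc for EEQYNSTYR), and the diagnostic
oxonium B ions.

The score is a bounded 0-100 heuristic built from matched-fragment counts:

    score = matched_by / (2*(n-1)) * 50
          + min(matched_Y_remnants, 5) * 8
          + 10 * [>= 2 oxonium ions matched]
          - 15 * [precursor m/z off by more than the MS1 tolerance]

(all matches within the MS2 ppm tolerance, floored at 0). The precursor
penalty makes a composition-inconsistent candidate score strictly below the
true one even when the truncated Y ladders share all low remnants; during a
search it never fires because candidates are precursor-filtered. The score
replaces the closed-source commercial engine used interactively in the
original workflow and is tuned only to deliver the same decisions on clean
spectra; no FDR machinery is attached, the report instead carries the
fragment evidence needed for manual review.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .chem import (
    DEFAULT_CONSTANTS,
    EMPTY_GLYCAN,
    GlycanComposition,
    Glycopeptide,
    MassConstants,
    Peptide,
    glycan_mass,
    glycopeptide_mass,
    oxonium_mz,
    peptide_mass,
)
from .digestion import DEFAULT_ENZYMES, annotate_sequons, digest
from .glycans import GlycanLibrary
from .spectra import Run, Spectrum, match_peak
from .triage import DEFAULT_PANEL, OxoniumPanel, is_glyco_spectrum

__all__ = [
    "FragmentIon",
    "GPSM",
    "SearchConfig",
    "generate_candidates",
    "theoretical_fragments",
    "oxonium_fragments",
    "y_remnant_path",
    "score_gpsm",
    "search",
    "expand_variable_mods",
]

#: Elemental mass of the CH6O3 neutral loss behind the m/z 138 HexNAc fragment.
_CH6O3 = 12.0 + 6 * 1.0078250319 + 3 * 15.9949146221


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical fragment: series b/y (backbone), Y (peptide+remnant),
    or B (oxonium)."""

    series: str
    index: int
    remnant: GlycanComposition
    charge: int
    mz: float
    label: str

    def __post_init__(self) -> None:
        if self.series not in ("b", "y", "Y", "B"):
            raise ValueError(f"unknown fragment series {self.series!r}")


@dataclass(frozen=True)
class GPSM:
    """A scored glycopeptide-spectrum match with its fragment evidence."""

    scan_id: str
    glycopeptide: Glycopeptide
    score: float
    precursor_mz: float | None
    precursor_charge: int | None
    precursor_ppm: float | None
    matched_fragments: tuple[tuple[FragmentIon, float, float], ...]
    site_localized: bool
    protein: str | None = None


@dataclass(frozen=True)
class SearchConfig:
    """Tolerances and search-space settings (defaults follow the reference
    acquisition/search protocol: 10 ppm MS1, 20 ppm MS2, two missed
    cleavages, Glu-C + trypsin, 15 ppm / 2-hit oxonium triage)."""

    ms1_tol_ppm: float = 10.0
    ms2_tol_ppm: float = 20.0
    max_missed: int = 2
    enzymes: tuple = DEFAULT_ENZYMES
    fragment_charges: tuple[int, ...] = (1, 2)
    y_depth: int = 8
    variable_mods: bool = True
    max_oxidations: int = 2
    panel: OxoniumPanel = DEFAULT_PANEL
    constants: MassConstants = DEFAULT_CONSTANTS


def y_remnant_path(glycan: GlycanComposition, depth: int = 8) -> list[GlycanComposition]:
    """Leading glycan remnants along a core-out trimming path.

    Order: chitobiose HexNAc (up to 2), core Hex (up to 3), remaining
    HexNAc, remaining Hex, Fuc, NeuAc; truncated to *depth* remnants
    (excluding the empty Y0 remnant, which callers add themselves).
    """
    steps: list[GlycanComposition] = []
    hn = min(glycan.hexnac, 2)
    hx = min(glycan.hex, 3)
    cur = dict(hexnac=0, hex=0, fuc=0, neuac=0)

    def push(key: str, upto: int) -> None:
        while cur[key] < upto:
            cur[key] += 1
            steps.append(GlycanComposition(**cur))

    push("hexnac", hn)
    push("hex", hx)
    push("hexnac", glycan.hexnac)
    push("hex", glycan.hex)
    push("fuc", glycan.fuc)
    push("neuac", glycan.neuac)
    return steps[:depth]


def oxonium_fragments(
    glycan: GlycanComposition, constants: MassConstants = DEFAULT_CONSTANTS
) -> list[tuple[str, float]]:
    """Diagnostic oxonium (B-type) ions expected for a composition."""
    out: list[tuple[str, float]] = []
    if glycan.hexnac >= 1:
        hexnac = GlycanComposition(hexnac=1)
        base = oxonium_mz(hexnac, constants=constants)
        out += [
            ("HexNAc", base),
            ("HexNAc-H2O", oxonium_mz(hexnac, 1, constants)),
            ("HexNAc-2H2O", oxonium_mz(hexnac, 2, constants)),
            ("HexNAc-CH6O3", base - _CH6O3),
        ]
        if glycan.hex >= 1:
            out.append(
                ("HexNAcHex", oxonium_mz(GlycanComposition(hexnac=1, hex=1), constants=constants))
            )
    if glycan.neuac >= 1:
        neuac = GlycanComposition(neuac=1)
        out += [
            ("NeuAc", oxonium_mz(neuac, constants=constants)),
            ("NeuAc-H2O", oxonium_mz(neuac, 1, constants)),
        ]
    return out


def theoretical_fragments(
    gp: Glycopeptide,
    charges: tuple[int, ...] = (1, 2),
    y_depth: int = 8,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> list[FragmentIon]:
    """All theoretical fragments of a glycopeptide at the given charges."""
    pep = gp.peptide
    n = len(pep)
    proton = constants.proton
    frags: list[FragmentIon] = []

    # backbone prefix/suffix neutral masses with modifications
    res = [constants.residues[a] for a in pep.sequence]
    modmass = [0.0] * (n + 1)
    for pos, name in pep.mods:
        modmass[pos] += constants.modifications[name]
    prefix = [0.0]
    for k in range(1, n + 1):
        prefix.append(prefix[-1] + res[k - 1] + modmass[k])
    total = prefix[n] + constants.water

    def emit(series: str, index: int, neutral: float, remnant=EMPTY_GLYCAN, suffix=""):
        for z in charges:
            frags.append(
                FragmentIon(
                    series,
                    index,
                    remnant,
                    z,
                    (neutral + z * proton) / z,
                    f"{series}{index}{suffix}" + ("" if z == 1 else f"^{z}"),
                )
            )

    for k in range(1, n):
        emit("b", k, prefix[k])
        emit("y", k, total - prefix[n - k])

    if gp.site is not None and not gp.glycan.is_empty:
        pmass = total
        # Y series: peptide + leading remnants (Y0 = bare peptide)
        emit("Y", 0, pmass, suffix="")
        for i, rem in enumerate(y_remnant_path(gp.glycan, y_depth), start=1):
            emit("Y", i, pmass + glycan_mass(rem, constants), rem, suffix=f"+{rem}")
        # site-spanning glyco-remnant b/y ions (localisation evidence)
        remnants = [GlycanComposition(hexnac=1)]
        if gp.glycan.hexnac >= 2:
            remnants.append(GlycanComposition(hexnac=2))
        for rem in remnants:
            rmass = glycan_mass(rem, constants)
            for k in range(gp.site, n):
                emit("b", k, prefix[k] + rmass, rem, suffix=f"+{rem}")
            for k in range(n - gp.site + 1, n):
                emit("y", k, total - prefix[n - k] + rmass, rem, suffix=f"+{rem}")
        for label, mz in oxonium_fragments(gp.glycan, constants):
            frags.append(FragmentIon("B", 0, EMPTY_GLYCAN, 1, mz, label))
    return frags


def _comp_key(c: GlycanComposition) -> tuple:
    return (c.total, c.hexnac, c.hex, c.fuc, c.neuac)


def generate_candidates(
    precursor_mz: float,
    charge: int,
    peptides: list[Peptide],
    library: GlycanLibrary,
    tol_ppm: float = 10.0,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> list[Glycopeptide]:
    """All glycopeptides (and bare peptides) matching the precursor.

    Peptides must carry sequon annotations; peptides without sequons are
    paired only with the empty glycan. Deterministically ordered by
    |precursor error|, then glycan size, then sequence.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    out: list[tuple[float, tuple, Glycopeptide]] = []

    def consider(gp: Glycopeptide) -> None:
        theo = (glycopeptide_mass(gp, constants) + charge * constants.proton) / charge
        ppm = (precursor_mz - theo) / theo * 1e6
        if abs(ppm) <= tol_ppm:
            out.append((abs(ppm), _comp_key(gp.glycan) + (gp.peptide.sequence, gp.peptide.start, gp.site or 0), gp))

    for pep in peptides:
        consider(Glycopeptide(pep, None))
        for site in pep.sequon_sites:
            for comp in library.compositions():
                consider(Glycopeptide(pep, site, comp))
    out.sort(key=lambda t: (t[0], t[1]))
    return [gp for _ppm, _key, gp in out]


def score_gpsm(
    spectrum: Spectrum,
    gp: Glycopeptide,
    tol_ppm: float = 20.0,
    ms1_tol_ppm: float = 10.0,
    charges: tuple[int, ...] = (1, 2),
    y_depth: int = 8,
    constants: MassConstants = DEFAULT_CONSTANTS,
    protein: str | None = None,
) -> GPSM:
    """Score one candidate against one MS2 spectrum (deterministic, 0-100)."""
    if spectrum.ms_level != 2:
        raise ValueError(f"scan {spectrum.scan_id}: scoring requires MS2")
    frags = theoretical_fragments(gp, charges, y_depth, constants)
    matched: list[tuple[FragmentIon, float, float]] = []
    backbone: set[tuple[str, int]] = set()
    y_remnants: set[GlycanComposition] = set()
    oxo: set[str] = set()
    localized = False
    for frag in frags:
        hit = match_peak(spectrum, frag.mz, tol_ppm)
        if hit is None:
            continue
        matched.append((frag, hit.mz, hit.intensity))
        if frag.series in ("b", "y"):
            if frag.remnant.is_empty:
                backbone.add((frag.series, frag.index))
            else:
                localized = True
        elif frag.series == "Y":
            y_remnants.add(frag.remnant)
        elif frag.series == "B":
            oxo.add(frag.label)

    n = len(gp.peptide)
    by_term = 50.0 * len(backbone) / (2 * (n - 1)) if n > 1 else 0.0
    score = by_term + 8.0 * min(len(y_remnants), 5) + (10.0 if len(oxo) >= 2 else 0.0)

    ppm = None
    if spectrum.precursor_mz is not None:
        neutral = glycopeptide_mass(gp, constants)
        zs = [spectrum.precursor_charge] if spectrum.precursor_charge else [1, 2, 3, 4]
        ppm = min(
            (
                (spectrum.precursor_mz - (neutral + z * constants.proton) / z)
                / ((neutral + z * constants.proton) / z)
                * 1e6
                for z in zs
            ),
            key=abs,
        )
        if abs(ppm) > ms1_tol_ppm:
            score -= 15.0
    score = min(100.0, max(0.0, score))
    return GPSM(
        scan_id=spectrum.scan_id,
        glycopeptide=gp,
        score=score,
        precursor_mz=spectrum.precursor_mz,
        precursor_charge=spectrum.precursor_charge,
        precursor_ppm=ppm,
        matched_fragments=tuple(matched),
        site_localized=localized,
        protein=protein,
    )


def expand_variable_mods(
    peptides: list[Peptide], max_oxidations: int = 2, n_term_acetyl: bool = True
) -> list[Peptide]:
    """Expand peptides into variable-modification forms.

    Variable mods searched: Met oxidation (up to *max_oxidations* per
    peptide) and acetylation of the protein N-terminus (peptides starting at
    position 1). The unmodified form is always first.
    """
    out = []
    for pep in peptides:
        mets = [i + 1 for i, a in enumerate(pep.sequence) if a == "M"]
        ox_choices: list[tuple[int, ...]] = [()]
        for k in range(1, min(max_oxidations, len(mets)) + 1):
            ox_choices += [c for c in itertools.combinations(mets, k)]
        ac_choices = [()]
        if n_term_acetyl and pep.start == 1:
            ac_choices.append(((1, "acetyl"),))
        for ox in ox_choices:
            for ac in ac_choices:
                mods = tuple(sorted(ac + tuple((p, "oxidation") for p in ox)))
                out.append(pep.with_mods(mods))
    return out


def search(
    run: Run,
    proteins: list[tuple[str, str]],
    library: GlycanLibrary,
    config: SearchConfig = SearchConfig(),
) -> list[GPSM]:
    """Triage + candidate generation + scoring for every MS2 in a run.

    Returns the best GPSM per triaged spectrum, ranked by score, then
    |precursor ppm|, then fewer glycan residues, then composition, then
    sequence (fully deterministic).
    """
    if not proteins:
        raise ValueError("search requires at least one protein sequence")
    if library is None or len(library) == 0:
        raise ValueError("search requires a non-empty glycan library")

    candidates: list[tuple[Peptide, str]] = []
    for desc, seq in proteins:
        peps = annotate_sequons(digest(seq, config.enzymes, config.max_missed), seq)
        if config.variable_mods:
            peps = expand_variable_mods(peps, config.max_oxidations)
        candidates += [(p, desc) for p in peps]

    protein_of = {id(p): d for p, d in candidates}
    peptides = [p for p, _d in candidates]

    results: list[GPSM] = []
    for spec in run.ms2():
        tri = is_glyco_spectrum(spec, config.panel)
        if not tri.is_glyco:
            continue
        charge = spec.precursor_charge or 2
        cands = generate_candidates(
            spec.precursor_mz, charge, peptides, library,
            config.ms1_tol_ppm, config.constants,
        )
        best: GPSM | None = None
        best_key = None
        for gp in cands:
            g = score_gpsm(
                spec, gp,
                tol_ppm=config.ms2_tol_ppm,
                ms1_tol_ppm=config.ms1_tol_ppm,
                charges=config.fragment_charges,
                y_depth=config.y_depth,
                constants=config.constants,
                protein=protein_of.get(id(gp.peptide)),
            )
            key = (
                -g.score,
                abs(g.precursor_ppm) if g.precursor_ppm is not None else 0.0,
                _comp_key(gp.glycan),
                gp.peptide.sequence,
                gp.peptide.start,
                gp.site or 0,
            )
            if best_key is None or key < best_key:
                best, best_key = g, key
        if best is not None:
            results.append(best)
    return results
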