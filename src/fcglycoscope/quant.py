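"""MS1 glycoform profiling and 18O site-occupancy quantification.

Glycoform profiling reads, per identified composition, the MS1 monoisotopic
peak height of the glycopeptide precursor (summed over charge states, apex
over the MS1 scans within a retention-time window of the MS2 trigger) and
normalises over the occupied compositions.

Site occupancy uses the PNGase-F/heavy-water chemistry: deglycosylation in
H2(18)O converts a formerly occupied Asn to Asp carrying one 18-O, shifting
the peptide by +2.98826 Da (deamidation +0.98402 plus the 18O-16O difference
+2.00425). At orbitrap resolving powers the labeled monoisotopic peak is not
separated from the M+3 isotopologue of the unlabeled (still-Asn) peptide, so
the labeled height is corrected by subtracting the predicted M+3 contribution
of the unlabeled envelope before forming

    occupancy = corrected_labeled / (corrected_labeled + unlabeled)

aggregated over charge states by intensity weighting. Peak heights (not
areas) are used throughout. Natural deamidation (+0.98402, 16-O) is excluded
from both numerator and denominator; a diagnostic flag is raised when its
peak exceeds 5% of the unlabeled height. The 3% light-water leakage of the
labeling reaction is not corrected for (bias < 1%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .chem import (
    DEFAULT_CONSTANTS,
    GlycanComposition,
    Glycopeptide,
    MassConstants,
    Peptide,
    glycan_elemental_composition,
    glycopeptide_mz,
    peptide_composition,
    peptide_mass,
)
from .gpsm import GPSM
from .spectra import Run, Spectrum, match_peak

__all__ = [
    "GlycoformProfile",
    "OccupancyResult",
    "isotope_envelope",
    "glycoform_profile",
    "occupancy_18O",
]

#: 13C-12C spacing used for aggregated isotopologue positions.
NEUTRON = 1.0033548

#: Aggregated isotope shift distributions (neutron-count, abundance) for the
#: elements occurring in peptides and glycans (IUPAC representative values).
_ELEMENT_ISOTOPES: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}


def _power_convolve(dist: np.ndarray, count: int, n_peaks: int) -> np.ndarray:
    """dist**count under convolution, truncated to n_peaks (binary power)."""
    result = np.array([1.0])
    base = dist.copy()
    while count:
        if count & 1:
            result = np.convolve(result, base)[:n_peaks]
        count >>= 1
        if count:
            base = np.convolve(base, base)[:n_peaks]
    return result


@lru_cache(maxsize=512)
def _envelope_cached(comp_items: tuple[tuple[str, int], ...], n_peaks: int) -> tuple[float, ...]:
    dist = np.array([1.0])
    for element, count in comp_items:
        if element not in _ELEMENT_ISOTOPES:
            raise ValueError(f"no isotope data for element {element!r}")
        if count < 0:
            raise ValueError(f"negative atom count for {element}")
        edist = np.asarray(_ELEMENT_ISOTOPES[element])
        dist = np.convolve(dist, _power_convolve(edist, count, n_peaks))[:n_peaks]
    dist = dist / dist.max()
    return tuple(float(x) for x in dist)


def isotope_envelope(molecule, n_peaks: int = 6) -> np.ndarray:
    """Aggregated isotopologue abundances, normalised to the base peak.

    *molecule* may be a peptide sequence, a :class:`Peptide`, a
    :class:`Glycopeptide`, a :class:`GlycanComposition`, or an elemental
    composition mapping (atom counts). Entry k is the relative abundance of
    the M+k isotopologue.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if isinstance(molecule, (str, Peptide)):
        comp = peptide_composition(molecule)
    elif isinstance(molecule, Glycopeptide):
        from .chem import glycopeptide_composition

        comp = glycopeptide_composition(molecule)
    elif isinstance(molecule, GlycanComposition):
        comp = glycan_elemental_composition(molecule)
    else:
        comp = dict(molecule)
    items = tuple(sorted((el, int(n)) for el, n in comp.items() if n))
    return np.asarray(_envelope_cached(items, n_peaks))


# ---------------------------------------------------------------------------
# glycoform profiling


@dataclass
class GlycoformProfile:
    """Relative abundances over occupied-site compositions at one site."""

    site: int | None
    fractions: dict[GlycanComposition, float]
    intensities: dict[GlycanComposition, dict[int, float]]
    n_excluded: int = 0

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if self.fractions and abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, not 1")

    @property
    def n_glycoforms(self) -> int:
        return len(self.fractions)


def _precursor_height(
    gpsm: GPSM,
    run: Run,
    charges: tuple[int, ...],
    tol_ppm: float,
    rt_window: float,
    constants: MassConstants,
) -> dict[int, float]:
    """Apex MS1 monoisotopic height per charge near the MS2 trigger."""
    ms2 = run.by_id(gpsm.scan_id)
    ms1_scans = run.ms1()
    if ms2.rt is not None:
        near = [s for s in ms1_scans if s.rt is not None and abs(s.rt - ms2.rt) <= rt_window]
        ms1_scans = near or ms1_scans
    heights: dict[int, float] = {}
    for z in charges:
        target = glycopeptide_mz(gpsm.glycopeptide, z, constants)
        best = 0.0
        for scan in ms1_scans:
            hit = match_peak(scan, target, tol_ppm)
            if hit is not None and hit.intensity > best:
                best = hit.intensity
        if best > 0:
            heights[z] = best
    return heights


def glycoform_profile(
    gpsms: list[GPSM],
    run: Run,
    charges: tuple[int, ...] = (2, 3),
    tol_ppm: float = 10.0,
    rt_window: float = 30.0,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> GlycoformProfile:
    """Build the per-site glycoform relative-abundance profile from GPSMs.

    All GPSMs must share one protein site. Per composition the supporting
    intensity is the apex (max over that composition's GPSMs) of the summed
    per-charge MS1 monoisotopic heights; fractions are normalised over the
    compositions seen.
    """
    glyco = [g for g in gpsms if g.glycopeptide.site is not None]
    sites = {g.glycopeptide.protein_site for g in glyco}
    if len(sites) > 1:
        raise ValueError(f"GPSMs span multiple sites: {sorted(sites)}")
    site = sites.pop() if sites else None

    support: dict[GlycanComposition, dict[int, float]] = {}
    apex: dict[GlycanComposition, float] = {}
    n_excluded = 0
    for g in glyco:
        heights = _precursor_height(g, run, charges, tol_ppm, rt_window, constants)
        if not heights:
            n_excluded += 1
            continue
        comp = g.glycopeptide.glycan
        total = sum(heights.values())
        if total > apex.get(comp, 0.0):
            apex[comp] = total
            support[comp] = heights
    total = sum(apex.values())
    fractions = {c: v / total for c, v in sorted(apex.items())} if total > 0 else {}
    return GlycoformProfile(site, fractions, support, n_excluded)


# ---------------------------------------------------------------------------
# 18O site occupancy


@dataclass
class OccupancyResult:
    """Occupied fraction of one sequon from an 18O deglycosylation run."""

    site: int | None
    occupied: float | None
    raw_heights: dict[int, dict[str, float]]
    corrected_labeled: dict[int, float]
    quantifiable: bool
    deamidation_warning: bool = False

    def __post_init__(self) -> None:
        if self.occupied is not None and not 0.0 <= self.occupied <= 1.0:
            raise ValueError(f"occupancy {self.occupied} outside [0, 1]")


def occupancy_18O(
    run: Run,
    peptide: Peptide | str,
    site: int | None = None,
    charges: tuple[int, ...] = (2, 3),
    tol_ppm: float = 10.0,
    correct_isotope: bool = True,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> OccupancyResult:
    """Quantify sequon occupancy from MS1 scans of a PNGase-F/H2(18)O digest.

    Heights are summed over all MS1 scans per charge state. With
    *correct_isotope* the predicted M+3 isotopologue of the unlabeled
    envelope is subtracted from the labeled monoisotopic height.
    """
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    shift_label = constants.modifications["deamidation_18O"]
    shift_deam = constants.modifications["deamidation"]
    neutral = peptide_mass(peptide, constants)
    envelope = isotope_envelope(peptide, n_peaks=4)
    m3_ratio = float(envelope[3]) if len(envelope) > 3 else 0.0

    raw: dict[int, dict[str, float]] = {}
    corrected: dict[int, float] = {}
    occ_num = occ_den = 0.0
    deam_warn = False
    ms1_scans = run.ms1()
    for z in charges:
        mz_un = (neutral + z * constants.proton) / z
        mz_lab = (neutral + shift_label + z * constants.proton) / z
        mz_deam = (neutral + shift_deam + z * constants.proton) / z
        h_un = h_lab = h_deam = 0.0
        for scan in ms1_scans:
            for target, add in ((mz_un, "un"), (mz_lab, "lab"), (mz_deam, "deam")):
                hit = match_peak(scan, target, tol_ppm)
                if hit is not None:
                    if add == "un":
                        h_un += hit.intensity
                    elif add == "lab":
                        h_lab += hit.intensity
                    else:
                        h_deam += hit.intensity
        if h_un == 0.0 and h_lab == 0.0:
            continue
        raw[z] = {"unlabeled": h_un, "labeled": h_lab, "deamidated": h_deam}
        corr = h_lab - (m3_ratio * h_un if correct_isotope else 0.0)
        corr = max(0.0, corr)
        corrected[z] = corr
        occ_num += corr
        occ_den += corr + h_un
        if h_un > 0 and h_deam > 0.05 * h_un:
            deam_warn = True

    if occ_den == 0.0:
        return OccupancyResult(site, None, raw, corrected, False, deam_warn)
    return OccupancyResult(site, occ_num / occ_den, raw, corrected, True, deam_warn)
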