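"""Oxonium-ion triage of MS2 spectra.

On the instrument, detecting two of the common low-mass carbohydrate oxonium
ions within 15 ppm triggered acquisition of a glycopeptide HCD scan; here the
identical rule runs as an offline filter over recorded MS2 spectra. The
default panel ships all seven reference ions; two hits within 15 ppm flag a
spectrum as glycopeptide-derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .spectra import Spectrum, match_peak

__all__ = ["OxoniumPanel", "TriageResult", "DEFAULT_PANEL", "is_glyco_spectrum"]

#: Reference m/z values of the diagnostic oxonium ions (singly protonated).
DEFAULT_OXONIUM_IONS: tuple[tuple[str, float], ...] = (
    ("HexNAc", 204.0867),
    ("HexNAc-CH6O3", 138.0545),
    ("HexNAcHex", 366.1396),
    ("HexNAc-2H2O", 168.0653),
    ("HexNAc-H2O", 186.0760),
    ("NeuAc", 292.1031),
    ("NeuAc-H2O", 274.0927),
)


@dataclass(frozen=True)
class OxoniumPanel:
    ions: tuple[tuple[str, float], ...] = DEFAULT_OXONIUM_IONS
    tol_ppm: float = 15.0
    min_hits: int = 2
    #: optional intensity floor relative to the base peak (0 disables it)
    min_relative_intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.min_hits < 1:
            raise ValueError("min_hits must be >= 1")
        if any(mz <= 0 for _l, mz in self.ions):
            raise ValueError("panel m/z values must be positive")
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")


DEFAULT_PANEL = OxoniumPanel()


@dataclass(frozen=True)
class TriageResult:
    is_glyco: bool
    matched_labels: tuple[str, ...]


def is_glyco_spectrum(spectrum: Spectrum, panel: OxoniumPanel = DEFAULT_PANEL) -> TriageResult:
    """Apply the two-of-the-panel oxonium rule to one MS2 spectrum."""
    if spectrum.ms_level != 2:
        raise ValueError(f"scan {spectrum.scan_id}: triage requires an MS2 spectrum")
    floor = panel.min_relative_intensity * spectrum.base_peak_intensity
    matched = []
    for label, mz in panel.ions:
        hit = match_peak(spectrum, mz, panel.tol_ppm)
        if hit is not None and hit.intensity >= floor:
            matched.append(label)
    return TriageResult(len(matched) >= panel.min_hits, tuple(matched))
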