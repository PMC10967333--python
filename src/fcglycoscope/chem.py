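"""Monoisotopic mass calculus for peptides, N-glycans and their ions.

All masses are monoisotopic and in daltons. Monosaccharides carry dehydrated
glycosyl-residue masses; attaching a glycan to an Asn side chain adds no
water, so the neutral mass of a glycopeptide is exactly
``peptide_mass + glycan_mass``. Charged species are protonated: m/z for
charge z is ``(M + z * proton) / z`` with the proton at 1.0072765 Da (the
electron mass is not separately subtracted; the resulting error is far below
the ppm tolerances used anywhere in the pipeline).

The mass table ships as a versioned JSON resource
(``resources/masses.json``) and can be overridden by loading a user table
with :func:`load_mass_constants`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources as _ilres
from typing import Mapping

__all__ = [
    "MassConstants",
    "GlycanComposition",
    "Peptide",
    "Glycopeptide",
    "DEFAULT_CONSTANTS",
    "load_mass_constants",
    "peptide_mass",
    "glycan_mass",
    "glycopeptide_mass",
    "peptide_mz",
    "glycopeptide_mz",
    "oxonium_mz",
    "peptide_composition",
    "glycan_elemental_composition",
    "glycopeptide_composition",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Elemental composition of each dehydrated monosaccharide residue.
MONOSACCHARIDE_FORMULAS: dict[str, dict[str, int]] = {
    "HexNAc": {"C": 8, "H": 13, "N": 1, "O": 5},
    "Hex": {"C": 6, "H": 10, "O": 5},
    "Fuc": {"C": 6, "H": 10, "O": 4},
    "NeuAc": {"C": 11, "H": 17, "N": 1, "O": 8},
}

#: Net elemental change of each supported modification.
MODIFICATION_FORMULAS: dict[str, dict[str, int]] = {
    "carbamidomethyl": {"C": 2, "H": 3, "N": 1, "O": 1},
    "oxidation": {"O": 1},
    "acetyl": {"C": 2, "H": 2, "O": 1},
    "deamidation": {"N": -1, "H": -1, "O": 1},
    # The heavy-water PNGase-F product: Asn -> Asp with one 18-O. For
    # envelope purposes the shape is that of the deamidated peptide; the
    # monoisotopic shift is carried by the mass table.
    "deamidation_18O": {"N": -1, "H": -1, "O": 1},
}


@dataclass(frozen=True)
class MassConstants:
    """Residue, modification and monosaccharide monoisotopic masses."""

    residues: Mapping[str, float]
    water: float
    proton: float
    electron: float
    modifications: Mapping[str, float]
    monosaccharides: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, m in {**self.residues, **self.monosaccharides}.items():
            if m <= 0:
                raise ValueError(f"non-positive mass for {name!r}: {m}")
        if self.water <= 0 or self.proton <= 0:
            raise ValueError("water and proton masses must be positive")
        d18 = self.modifications["deamidation_18O"] - self.modifications["deamidation"]
        if abs(d18 - 2.0042464) > 1e-4:
            raise ValueError(
                "deamidation_18O - deamidation must equal the 18O-16O mass "
                f"difference (2.00425 Da), got {d18:.5f}"
            )


def load_mass_constants(path: str | None = None) -> MassConstants:
    """Load a mass table from JSON (the packaged table when *path* is None)."""
    if path is None:
        text = (
            _ilres.files("fcglycoscope.resources").joinpath("masses.json").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    return MassConstants(
        residues=dict(raw["residues"]),
        water=float(raw["water"]),
        proton=float(raw["proton"]),
        electron=float(raw["electron"]),
        modifications=dict(raw["modifications"]),
        monosaccharides=dict(raw["monosaccharides"]),
    )


DEFAULT_CONSTANTS = load_mass_constants()

_MONO_ATTRS = (("HexNAc", "hexnac"), ("Hex", "hex"), ("Fuc", "fuc"), ("NeuAc", "neuac"))
_COMP_RE = re.compile(r"(HexNAc|Hex|Fuc|NeuAc)(\d+)")


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Counts of monosaccharide classes making up an N-glycan.

    Composition only — no topology or linkage. ``Fuc`` is generic
    deoxyhexose and ``NeuAc`` generic N-acetylneuraminic acid.
    """

    hexnac: int = 0
    hex: int = 0
    fuc: int = 0
    neuac: int = 0

    def __post_init__(self) -> None:
        for name, count in self.counts().items():
            if not isinstance(count, int) or count < 0:
                raise ValueError(f"negative or non-integer {name} count: {count!r}")

    def counts(self) -> dict[str, int]:
        return {"HexNAc": self.hexnac, "Hex": self.hex, "Fuc": self.fuc, "NeuAc": self.neuac}

    @property
    def is_empty(self) -> bool:
        return self.total == 0

    @property
    def total(self) -> int:
        return self.hexnac + self.hex + self.fuc + self.neuac

    def __str__(self) -> str:
        if self.is_empty:
            return "none"
        return "".join(f"{n}{c}" for n, c in self.counts().items() if c > 0)

    @classmethod
    def from_string(cls, text: str) -> "GlycanComposition":
        """Parse e.g. ``"HexNAc4Hex3Fuc1"`` (also accepts ``"none"``)."""
        text = text.strip()
        if text in ("", "none", "-"):
            return cls()
        counts: dict[str, int] = {}
        consumed = 0
        for m in _COMP_RE.finditer(text):
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2))
            consumed += len(m.group(0))
        if consumed != len(text):
            raise ValueError(f"unparseable glycan composition: {text!r}")
        return cls(
            hexnac=counts.get("HexNAc", 0),
            hex=counts.get("Hex", 0),
            fuc=counts.get("Fuc", 0),
            neuac=counts.get("NeuAc", 0),
        )


EMPTY_GLYCAN = GlycanComposition()


@dataclass(frozen=True)
class Peptide:
    """A digested peptide with 1-based inclusive protein coordinates.

    ``mods`` is a tuple of ``(position, modification_name)`` with positions in
     1..len(sequence); position 1 also hosts N-terminal modifications.
    ``sequon_sites`` lists positions (within the peptide) of Asn residues in
    valid N-glycosylation sequons, judged against the parent protein.
    """

    sequence: str
    start: int = 1
    end: int = 0
    mods: tuple[tuple[int, str], ...] = ()
    missed_cleavages: int = 0
    sequon_sites: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        if self.end == 0:
            object.__setattr__(self, "end", self.start + len(self.sequence) - 1)
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"coordinates {self.start}..{self.end} inconsistent with "
                f"length {len(self.sequence)}"
            )
        for pos, name in self.mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"modification position {pos} outside peptide")
        for pos in self.sequon_sites:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"sequon position {pos} outside peptide")

    def __len__(self) -> int:
        return len(self.sequence)

    def with_mods(self, mods: tuple[tuple[int, str], ...]) -> "Peptide":
        return Peptide(
            self.sequence, self.start, self.end, tuple(sorted(mods)),
            self.missed_cleavages, self.sequon_sites,
        )


@dataclass(frozen=True)
class Glycopeptide:
    """A peptide with a glycan composition at one sequon Asn.

    ``site`` is the 1-based position within the peptide; ``None`` marks a
    bare (unglycosylated) peptide candidate, in which case the glycan is
    empty.
    """

    peptide: Peptide
    site: int | None
    glycan: GlycanComposition = EMPTY_GLYCAN

    def __post_init__(self) -> None:
        if self.site is None:
            if not self.glycan.is_empty:
                raise ValueError("glycan attached without a site")
            return
        if not 1 <= self.site <= len(self.peptide):
            raise ValueError(f"site {self.site} outside peptide")
        if self.peptide.sequence[self.site - 1] != "N":
            raise ValueError(
                f"site {self.site} is {self.peptide.sequence[self.site - 1]!r}, not N"
            )

    @property
    def protein_site(self) -> int | None:
        """Site position in protein coordinates (e.g. 297 for Asn297)."""
        if self.site is None:
            return None
        return self.peptide.start + self.site - 1


# ---------------------------------------------------------------------------
# mass arithmetic


def peptide_mass(peptide: Peptide | str, constants: MassConstants = DEFAULT_CONSTANTS) -> float:
    """Neutral monoisotopic mass: residue masses + modification masses + water."""
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    total = constants.water
    for i, letter in enumerate(peptide.sequence):
        try:
            total += constants.residues[letter]
        except KeyError:
            raise ValueError(
                f"unknown residue {letter!r} at position {i + 1} of "
                f"{peptide.sequence!r}"
            ) from None
    for _pos, name in peptide.mods:
        try:
            total += constants.modifications[name]
        except KeyError:
            raise ValueError(f"unknown modification {name!r}") from None
    return total


def glycan_mass(glycan: GlycanComposition, constants: MassConstants = DEFAULT_CONSTANTS) -> float:
    """Sum of dehydrated monosaccharide residue masses (0 for the empty glycan)."""
    return sum(
        count * constants.monosaccharides[name] for name, count in glycan.counts().items()
    )


def glycopeptide_mass(gp: Glycopeptide, constants: MassConstants = DEFAULT_CONSTANTS) -> float:
    """Neutral mass; additive because glycan attachment is anhydrous."""
    return peptide_mass(gp.peptide, constants) + glycan_mass(gp.glycan, constants)


def _mz(neutral: float, charge: int, constants: MassConstants) -> float:
    if not isinstance(charge, int) or charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge!r}")
    return (neutral + charge * constants.proton) / charge


def peptide_mz(peptide: Peptide | str, charge: int, constants: MassConstants = DEFAULT_CONSTANTS) -> float:
    return _mz(peptide_mass(peptide, constants), charge, constants)


def glycopeptide_mz(gp: Glycopeptide, charge: int, constants: MassConstants = DEFAULT_CONSTANTS) -> float:
    """Protonated m/z of the intact glycopeptide at the given charge."""
    return _mz(glycopeptide_mass(gp, constants), charge, constants)


def oxonium_mz(
    glycan: GlycanComposition,
    water_losses: int = 0,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> float:
    """Singly charged B-type oxonium ion m/z for a (partial) glycan.

    The bare composition gives the classic oxonium (e.g. HexNAc -> 204.0866);
    ``water_losses`` subtracts that many waters for the dehydrated fragment
    variants (HexNAc-H2O at 186.076, HexNAc-2H2O at 168.065).
    """
    if glycan.is_empty:
        raise ValueError("oxonium ion of an empty composition is undefined")
    if water_losses < 0:
        raise ValueError("water_losses must be >= 0")
    return glycan_mass(glycan, constants) + constants.proton - water_losses * constants.water


# ---------------------------------------------------------------------------
# elemental compositions (used by the isotope-envelope machinery)


def _add_formula(target: dict[str, int], formula: Mapping[str, int], times: int = 1) -> None:
    for el, n in formula.items():
        target[el] = target.get(el, 0) + n * times
        if target[el] == 0:
            del target[el]


def peptide_composition(peptide: Peptide | str) -> dict[str, int]:
    """Elemental composition (atom counts) of a neutral peptide with mods."""
    from pyteomics import mass as _pmass

    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    for i, letter in enumerate(peptide.sequence):
        if letter not in AMINO_ACIDS:
            raise ValueError(
                f"unknown residue {letter!r} at position {i + 1} of "
                f"{peptide.sequence!r}"
            )
    comp = dict(_pmass.Composition(sequence=peptide.sequence))
    for _pos, name in peptide.mods:
        try:
            _add_formula(comp, MODIFICATION_FORMULAS[name])
        except KeyError:
            raise ValueError(f"unknown modification {name!r}") from None
    return comp


def glycan_elemental_composition(glycan: GlycanComposition) -> dict[str, int]:
    comp: dict[str, int] = {}
    for name, count in glycan.counts().items():
        _add_formula(comp, MONOSACCHARIDE_FORMULAS[name], count)
    return comp


def glycopeptide_composition(gp: Glycopeptide) -> dict[str, int]:
    comp = peptide_composition(gp.peptide)
    _add_formula(comp, glycan_elemental_composition(gp.glycan))
    return comp
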