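"""N-glycan composition library, shorthand nomenclature and class taxonomy.

Ships a documented ~40-entry human/plant-relevant composition library (TSV
resource) with the standard IgG shorthands (G0, G0F, ..., G2S1F, Man5-Man9,
monoHexNAc). Classification into oligomannose / hybrid / complex / other is
a stated heuristic on monosaccharide counts: compositions alone cannot
distinguish topological isomers (e.g. bisecting GlcNAc from an antenna), so
reports flag the class as count-derived.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources as _ilres
from io import StringIO
from pathlib import Path

from .chem import DEFAULT_CONSTANTS, GlycanComposition, glycan_mass

__all__ = [
    "GlycanRecord",
    "GlycanLibrary",
    "GLYCAN_CLASSES",
    "classify",
    "default_library",
    "load_library",
    "shorthand_to_composition",
]

GLYCAN_CLASSES = ("oligomannose", "complex", "hybrid", "other")


def classify(composition: GlycanComposition) -> str:
    """Count-based N-glycan class heuristic.

    - HexNAc=2 with Hex>=5: oligomannose (Man5 and larger).
    - HexNAc=3 with Hex>=5 and no sialic acid: hybrid (one processed antenna
      next to an unsubstituted mannose arm).
    - any other HexNAc>=3: complex.
    - everything else (monoHexNAc, paucimannose cores, chitobiose stubs):
      "other".
    """
    if composition.is_empty:
        raise ValueError("cannot classify an empty composition")
    if composition.hexnac == 2 and composition.hex >= 5:
        return "oligomannose"
    if composition.hexnac == 3 and composition.hex >= 5 and composition.neuac == 0:
        return "hybrid"
    if composition.hexnac >= 3:
        return "complex"
    return "other"


@dataclass(frozen=True)
class GlycanRecord:
    composition: GlycanComposition
    shorthand: str | None
    glycan_class: str

    def __post_init__(self) -> None:
        if self.glycan_class not in GLYCAN_CLASSES:
            raise ValueError(f"unknown glycan class {self.glycan_class!r}")


class GlycanLibrary:
    """A searchable set of glycan compositions with optional shorthands."""

    def __init__(self, records: list[GlycanRecord], provenance: str = ""):
        self.records = list(records)
        self.provenance = provenance
        self._by_comp: dict[GlycanComposition, GlycanRecord] = {}
        self._by_name: dict[str, GlycanRecord] = {}
        for rec in self.records:
            if rec.composition in self._by_comp:
                raise ValueError(f"duplicate composition {rec.composition}")
            if glycan_mass(rec.composition, DEFAULT_CONSTANTS) <= 0:
                raise ValueError(f"non-positive mass composition {rec.composition}")
            self._by_comp[rec.composition] = rec
            if rec.shorthand:
                if rec.shorthand in self._by_name:
                    raise ValueError(f"duplicate shorthand {rec.shorthand!r}")
                self._by_name[rec.shorthand] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def compositions(self) -> list[GlycanComposition]:
        return [r.composition for r in self.records]

    def shorthand_to_composition(self, name: str) -> GlycanComposition:
        try:
            return self._by_name[name].composition
        except KeyError:
            known = ", ".join(sorted(self._by_name))
            raise KeyError(f"unknown glycan shorthand {name!r}; known: {known}") from None

    def shorthand_for(self, composition: GlycanComposition) -> str | None:
        rec = self._by_comp.get(composition)
        return rec.shorthand if rec else None

    def record_for(self, composition: GlycanComposition) -> GlycanRecord | None:
        return self._by_comp.get(composition)

    def class_of(self, composition: GlycanComposition) -> str:
        rec = self._by_comp.get(composition)
        return rec.glycan_class if rec else classify(composition)


def _parse_rows(rows, provenance: str) -> GlycanLibrary:
    records = []
    for row in rows:
        comp = GlycanComposition(
            hexnac=int(row["hexnac"]),
            hex=int(row["hex"]),
            fuc=int(row.get("fuc") or 0),
            neuac=int(row.get("neuac") or 0),
        )
        shorthand = (row.get("shorthand") or "").strip() or None
        override = (row.get("class_override") or "").strip()
        records.append(GlycanRecord(comp, shorthand, override or classify(comp)))
    return GlycanLibrary(records, provenance)


def load_library(path: str | Path) -> GlycanLibrary:
    """Load a user library: TSV with columns shorthand, hexnac, hex, fuc, neuac
    and optional class_override."""
    with open(path, newline="") as fh:
        return _parse_rows(csv.DictReader(fh, delimiter="\t"), provenance=str(path))


_DEFAULT: GlycanLibrary | None = None


def default_library() -> GlycanLibrary:
    """The packaged composition library (lazy singleton)."""
    global _DEFAULT
    if _DEFAULT is None:
        text = (
            _ilres.files("fcglycoscope.resources")
            .joinpath("glycan_library.tsv")
            .read_text()
        )
        _DEFAULT = _parse_rows(
            csv.DictReader(StringIO(text), delimiter="\t"),
            provenance="fcglycoscope packaged library v1",
        )
    return _DEFAULT


def shorthand_to_composition(name: str) -> GlycanComposition:
    """Shorthand lookup against the packaged library."""
    return default_library().shorthand_to_composition(name)
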