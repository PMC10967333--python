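"""In-silico proteolysis and N-glycosylation sequon discovery.

The digest models a combined Glu-C + trypsin reaction: cleavage sites from
both enzymes are pooled into one site set and the missed-cleavage budget is
shared across the union. Trypsin cuts C-terminal to K/R but not before
proline; Glu-C cuts C-terminal to E only (both proline flags configurable).

Sequons follow the N-X-S/T rule with X != P.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .chem import AMINO_ACIDS, Peptide

__all__ = [
    "EnzymeRule",
    "TRYPSIN",
    "GLUC",
    "SequonSite",
    "cleavage_sites",
    "digest",
    "find_sequons",
    "annotate_sequons",
    "read_fasta",
    "write_fasta",
]


@dataclass(frozen=True)
class EnzymeRule:
    """C-terminal cleavage specificity of one protease."""

    name: str
    cleaves_after: frozenset[str]
    blocked_by_next_proline: bool = False

    def __post_init__(self) -> None:
        if not self.cleaves_after:
            raise ValueError("cleaves_after must be non-empty")


TRYPSIN = EnzymeRule("trypsin", frozenset("KR"), blocked_by_next_proline=True)
GLUC = EnzymeRule("glu-c", frozenset("E"), blocked_by_next_proline=False)
DEFAULT_ENZYMES = (GLUC, TRYPSIN)


@dataclass(frozen=True)
class SequonSite:
    """One N-glycosylation sequon, 1-based protein position of the Asn."""

    protein_position: int
    sequon: str

    def __post_init__(self) -> None:
        s = self.sequon
        if len(s) != 3 or s[0] != "N" or s[1] == "P" or s[2] not in "ST":
            raise ValueError(f"not a valid N-X-S/T sequon: {s!r}")


def cleavage_sites(protein: str, rules=DEFAULT_ENZYMES) -> list[int]:
    """Positions i (1-based, cut after residue i) of the pooled site set."""
    sites = set()
    for rule in rules:
        for i in range(len(protein) - 1):
            if protein[i] in rule.cleaves_after:
                if rule.blocked_by_next_proline and protein[i + 1] == "P":
                    continue
                sites.add(i + 1)
    return sorted(sites)


def digest(protein: str, rules=DEFAULT_ENZYMES, max_missed: int = 2) -> list[Peptide]:
    """Fully specific digest with up to *max_missed* internal cleavage sites.

    Peptides are returned in coordinate order (then by length) with 1-based
    inclusive coordinates and their missed-cleavage count.
    """
    if not protein:
        raise ValueError("protein sequence must be non-empty")
    bad = set(protein) - AMINO_ACIDS
    if bad:
        raise ValueError(f"unknown residues in protein: {sorted(bad)}")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    boundaries = [0] + cleavage_sites(protein, rules) + [len(protein)]
    peptides = []
    for a in range(len(boundaries) - 1):
        for b in range(a + 1, min(a + 2 + max_missed, len(boundaries))):
            start, end = boundaries[a] + 1, boundaries[b]
            peptides.append(
                Peptide(
                    protein[start - 1 : end],
                    start=start,
                    end=end,
                    missed_cleavages=b - a - 1,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def find_sequons(protein: str) -> list[SequonSite]:
    """All N-X-S/T (X != P) sites, 1-based, in protein order."""
    out = []
    for i in range(len(protein) - 2):
        if protein[i] == "N" and protein[i + 1] != "P" and protein[i + 2] in "ST":
            out.append(SequonSite(i + 1, protein[i : i + 3]))
    return out


def annotate_sequons(peptides: list[Peptide], protein: str) -> list[Peptide]:
    """Attach sequon positions (peptide-local) judged on the parent protein.

    Judging on the protein keeps sequons whose X or S/T residue falls in the
    next peptide.
    """
    positions = [s.protein_position for s in find_sequons(protein)]
    out = []
    for pep in peptides:
        local = tuple(
            p - pep.start + 1 for p in positions if pep.start <= p <= pep.end
        )
        out.append(
            Peptide(pep.sequence, pep.start, pep.end, pep.mods, pep.missed_cleavages, local)
        )
    return out


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a plain multi-record FASTA as (description, sequence) pairs."""
    from pyteomics import fasta as _fasta

    with open(path) as fh:
        return [(entry.description, entry.sequence) for entry in _fasta.read(fh)]


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for desc, seq in records:
            fh.write(f">{desc}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
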