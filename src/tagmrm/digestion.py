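"""In-silico tryptic digestion and biomarker-candidate selection.

Trypsin cleaves C-terminal to lysine (K) or arginine (R) unless the next
residue is proline — the canonical rule, with no further exceptions.  Products
are reported with 1-based inclusive coordinates in the parent protein and a
missed-cleavage count, and flagged for the features that matter when choosing
a fixed-charge-derivatization target: a C-terminal lysine (whose ε-amine the
tag condenses with), methionine (oxidation-prone; a warning, not an
exclusion) and cysteine (alkylated during preparation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .chem import STANDARD_RESIDUES

__all__ = [
    "DigestPeptide",
    "SelectionCriteria",
    "digest",
    "select_candidates",
    "read_fasta",
]


@dataclass(frozen=True)
class DigestPeptide:
    """A digestion product with parent coordinates and selection flags."""

    sequence: str
    start: int  # 1-based inclusive
    end: int
    missed_cleavages: int
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("coordinates inconsistent with sequence length")

    @property
    def taggable(self) -> bool:
        return "taggable" in self.flags


@dataclass(frozen=True)
class SelectionCriteria:
    min_len: int = 5
    max_len: int = 25
    require_c_term_K: bool = True
    flag_Met: bool = True
    require_unique: bool = False

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")


def _validate(sequence: str) -> None:
    for ch in sequence:
        if ch not in STANDARD_RESIDUES:
            raise ValueError(f"unknown residue letter {ch!r}")


def _peptide_flags(sequence: str) -> frozenset[str]:
    flags = set()
    if sequence.endswith("K"):
        flags.update({"c_term_K", "taggable"})
    if sequence.endswith("R"):
        flags.add("c_term_R")
    if "M" in sequence:
        flags.add("contains_M")
    if "C" in sequence:
        flags.add("contains_C")
    return frozenset(flags)


def cleavage_sites(sequence: str) -> list[int]:
    """0-based positions i such that trypsin cuts between i and i+1."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(protein: str, max_missed: int = 0) -> list[DigestPeptide]:
    """All tryptic products of ``protein`` with 0..``max_missed`` missed cleavages.

    Returned sorted by start coordinate, then by length; coordinates are
    1-based inclusive in the parent.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    _validate(protein)
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    cuts = cleavage_sites(protein)
    # segment boundaries: starts of fully-cleaved products (0-based)
    starts = [0] + [i + 1 for i in cuts]
    ends = [i for i in cuts] + [len(protein) - 1]
    out: list[DigestPeptide] = []
    nseg = len(starts)
    for i in range(nseg):
        for j in range(i, min(i + max_missed + 1, nseg)):
            s, e = starts[i], ends[j]
            seq = protein[s : e + 1]
            out.append(
                DigestPeptide(
                    sequence=seq,
                    start=s + 1,
                    end=e + 1,
                    missed_cleavages=j - i,
                    flags=_peptide_flags(seq),
                )
            )
    out.sort(key=lambda p: (p.start, len(p.sequence)))
    return out


def select_candidates(
    peptides: list[DigestPeptide],
    criteria: SelectionCriteria,
    proteome: dict[str, str] | None = None,
) -> list[DigestPeptide]:
    """Filter digestion products to fixed-charge-tag candidates.

    Keeps peptides within the length bounds and (if required) ending in
    lysine.  Methionine content is a flag, not an exclusion — an
    oxidation-stable Met peptide can still be a usable target.  When a
    proteome is supplied and ``require_unique`` is set, only peptides whose
    sequence occurs exactly once across all supplied proteins (exact substring
    count, no I/L equivalence) are kept; otherwise a ``unique``/``shared``
    flag is attached.
    """
    out: list[DigestPeptide] = []
    for pep in peptides:
        n = len(pep.sequence)
        if not (criteria.min_len <= n <= criteria.max_len):
            continue
        if criteria.require_c_term_K and "c_term_K" not in pep.flags:
            continue
        flags = set(pep.flags)
        if proteome is not None:
            count = sum(_count_occurrences(prot, pep.sequence) for prot in proteome.values())
            flags.add("unique" if count == 1 else "shared")
            if criteria.require_unique and count != 1:
                continue
        out.append(
            DigestPeptide(pep.sequence, pep.start, pep.end, pep.missed_cleavages, frozenset(flags))
        )
    return out


def _count_occurrences(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1  # overlapping occurrences count


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA → {record id: uppercase sequence}, '*' stripped."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper().replace("*", "")
    return records
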