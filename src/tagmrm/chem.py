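"""Monoisotopic mass calculus for peptides carrying fixed-charge tags.

The central object is a :class:`Peptide` — a sequence of the 20 standard
residues plus site-localized :class:`Modification` objects.  A modification is
an elemental-composition delta together with an *intrinsic* (fixed) charge it
contributes; ordinary modifications (oxidation, carbamidomethylation) carry
zero fixed charge, while an ionization-enhancer tag such as the
2,4,6-triphenylpyridinium group formed by condensing a pyrylium salt with a
lysine ε-amine carries a permanent +1.

Charge bookkeeping is the point of this module: an ion of total charge ``z``
that already carries ``f`` fixed charges acquires only ``z − f`` protons, so

    m/z = (M_atoms + (z − f)·m_proton) / z

where ``M_atoms`` is the monoisotopic mass of the species' atoms (electron
mass neglected; the ~0.55 mDa error is far below the ±0.1 m/z matching
tolerance of unit-resolution triple-quadrupole data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from pyteomics import mass as _pmass

__all__ = [
    "PROTON_MASS",
    "ElementalComposition",
    "Modification",
    "Peptide",
    "Ion",
    "TPP",
    "OXIDATION",
    "CARBAMIDOMETHYL",
    "BUILTIN_MODS",
    "neutral_mass",
    "precursor_mz",
    "fragment_mz",
    "reporter_mz",
    "round_half_away",
    "load_modifications",
]

#: Mass of a proton in Da; the value conventionally used for 2-dp MRM lists.
PROTON_MASS = 1.007276

_WATER = {"H": 2, "O": 1}

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


def _element_mass(symbol: str) -> float:
    try:
        return _pmass.nist_mass[symbol][0][0]
    except KeyError:
        raise ValueError(f"unknown element symbol {symbol!r}") from None


class ElementalComposition:
    """A signed element → count map with element-wise arithmetic.

    Physical species have non-negative counts; modification *deltas* may be
    signed (e.g. a condensation that expels water).
    """

    __slots__ = ("counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        merged: dict[str, int] = {}
        for src in (counts or {}), kwargs:
            for el, n in src.items():
                merged[el] = merged.get(el, 0) + int(n)
        self.counts = {el: n for el, n in merged.items() if n != 0}
        for el in self.counts:
            _element_mass(el)  # validate symbols eagerly

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = dict(self.counts)
        for el, n in other.counts.items():
            out[el] = out.get(el, 0) + n
        return ElementalComposition(out)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        return self + ElementalComposition({el: -n for el, n in other.counts.items()})

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ElementalComposition) and self.counts == other.counts

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __repr__(self) -> str:
        inner = "".join(f"{el}{n}" for el, n in sorted(self.counts.items()))
        return f"ElementalComposition({inner or 'empty'})"

    def mass(self) -> float:
        """Monoisotopic mass in Da (sum of most-abundant-isotope masses)."""
        return sum(_element_mass(el) * n for el, n in self.counts.items())


@dataclass(frozen=True)
class Modification:
    """A site-localized chemical modification.

    Parameters
    ----------
    name : str
    delta : ElementalComposition
        Net change in the peptide's atomic composition.
    fixed_charge_delta : int
        Permanent charge the modification contributes (0 for ordinary
        modifications, 1 for a pyridinium fixed-charge tag).
    site_residues : str
        Residue letters the modification may occupy.
    reporter : ElementalComposition, optional
        Atomic composition of the tag's reporter cation, if it has one
        (for TPP: protonated 2,4,6-triphenylpyridine, C23H18N+).
    reporter_charge : int
        Charge of the reporter cation.
    """

    name: str
    delta: ElementalComposition
    fixed_charge_delta: int = 0
    site_residues: str = ""
    reporter: ElementalComposition | None = None
    reporter_charge: int = 1

    def __post_init__(self) -> None:
        if self.fixed_charge_delta < 0:
            raise ValueError("fixed_charge_delta must be >= 0")

    def allows_site(self, residue: str) -> bool:
        return not self.site_residues or residue in self.site_residues


#: 2,4,6-triphenylpyridinium fixed-charge tag on a lysine ε-amine.  The
#: pyrylium reagent (C23H17O+) condenses with the amine expelling water that
#: takes two amine hydrogens, so the net peptide delta is +C23H15 and +1 fixed
#: charge.  Its reporter is the protonated triphenylpyridine cation.
TPP = Modification(
    name="TPP",
    delta=ElementalComposition(C=23, H=15),
    fixed_charge_delta=1,
    site_residues="K",
    reporter=ElementalComposition(C=23, H=18, N=1),
    reporter_charge=1,
)

OXIDATION = Modification(
    name="Oxidation", delta=ElementalComposition(O=1), site_residues="M"
)

CARBAMIDOMETHYL = Modification(
    name="Carbamidomethyl", delta=ElementalComposition(C=2, H=3, N=1, O=1),
    site_residues="C",
)

BUILTIN_MODS: dict[str, Modification] = {
    "TPP": TPP,
    "Oxidation": OXIDATION,
    "Carbamidomethyl": CARBAMIDOMETHYL,
}


def load_modifications(path) -> dict[str, Modification]:
    """Read modification definitions from a YAML config file.

    Each entry maps a name to ``delta`` (element → signed count),
    ``fixed_charge`` (default 0), ``sites`` (residue letters) and optionally
    ``reporter`` (element → count) with ``reporter_charge``.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    mods: dict[str, Modification] = {}
    for name, entry in raw.items():
        reporter = entry.get("reporter")
        mods[name] = Modification(
            name=name,
            delta=ElementalComposition(entry["delta"]),
            fixed_charge_delta=int(entry.get("fixed_charge", 0)),
            site_residues=str(entry.get("sites", "")),
            reporter=ElementalComposition(reporter) if reporter else None,
            reporter_charge=int(entry.get("reporter_charge", 1)),
        )
    return mods


@dataclass(frozen=True)
class Peptide:
    """A residue sequence with site-localized modifications.

    ``mods`` maps 1-based residue positions to modifications; each position
    may carry at most one modification and the residue must satisfy the
    modification's site rule.
    """

    sequence: str
    mods: tuple[tuple[int, Modification], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("zero-length peptide")
        for ch in self.sequence:
            if ch not in STANDARD_RESIDUES:
                raise ValueError(f"unknown residue letter {ch!r}")
        seen: set[int] = set()
        for pos, mod in self.mods:
            if not (1 <= pos <= len(self.sequence)):
                raise ValueError(f"modification position {pos} out of range")
            if pos in seen:
                raise ValueError(f"more than one modification at position {pos}")
            seen.add(pos)
            residue = self.sequence[pos - 1]
            if not mod.allows_site(residue):
                raise ValueError(
                    f"{mod.name} not allowed on residue {residue!r} at {pos}"
                )

    @classmethod
    def from_mods(cls, sequence: str, mods: Iterable[tuple[int, Modification]] = ()) -> "Peptide":
        return cls(sequence, tuple(mods))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def fixed_charge(self) -> int:
        return sum(m.fixed_charge_delta for _, m in self.mods)

    def composition(self) -> ElementalComposition:
        """Atomic composition of the intact (possibly cationic) species."""
        comp = ElementalComposition(_WATER)
        for ch in self.sequence:
            comp = comp + _residue_composition(ch)
        for _, mod in self.mods:
            comp = comp + mod.delta
        return comp


@dataclass(frozen=True)
class Ion:
    """A precursor, backbone-fragment, or reporter ion with its m/z."""

    series: str  # 'precursor' | 'b' | 'y' | 'reporter'
    index: int | None
    total_charge: int
    mz: float


def _residue_composition(letter: str) -> ElementalComposition:
    comp = _pmass.std_aa_comp[letter]
    return ElementalComposition({el: n for el, n in comp.items()})


def neutral_mass(peptide: Peptide) -> float:
    """Monoisotopic mass of the peptide's atoms in Da.

    For a species carrying fixed charges this is the mass of the cation's
    atoms — the protons that would bring it to a given total charge are added
    by :func:`precursor_mz` / :func:`fragment_mz`, never here.
    """
    return peptide.composition().mass()


def precursor_mz(peptide: Peptide, total_charge: int) -> float:
    """m/z of the intact peptide at ``total_charge``.

    Protons are added only beyond the peptide's fixed charge: with fixed
    charge ``f``, m/z = (M + (z − f)·m_proton) / z.
    """
    f = peptide.fixed_charge
    if total_charge < 1:
        raise ValueError("total_charge must be >= 1")
    if total_charge < f:
        raise ValueError("fewer charges than fixed charges")
    return (neutral_mass(peptide) + (total_charge - f) * PROTON_MASS) / total_charge


def _fragment_residue_positions(peptide: Peptide, series: str, index: int) -> range:
    n = len(peptide)
    if not (1 <= index <= n - 1):
        raise ValueError(f"fragment index {index} out of range for length {n}")
    if series == "b":
        return range(1, index + 1)
    if series == "y":
        return range(n - index + 1, n + 1)
    raise ValueError(f"unsupported fragment series {series!r}")


def fragment_mz(peptide: Peptide, series: str, index: int, total_charge: int) -> float:
    """m/z of a b- or y-series fragment.

    A y_i fragment comprises the C-terminal ``i`` residues plus water; a b_i
    fragment the N-terminal ``i`` residues.  Site-localized modifications are
    carried by whichever fragment contains their residue, and the fragment's
    fixed charge reduces the number of protons added exactly as for the
    precursor.
    """
    positions = _fragment_residue_positions(peptide, series, index)
    comp = ElementalComposition(_WATER) if series == "y" else ElementalComposition()
    for pos in positions:
        comp = comp + _residue_composition(peptide.sequence[pos - 1])
    f = 0
    for pos, mod in peptide.mods:
        if pos in positions:
            comp = comp + mod.delta
            f += mod.fixed_charge_delta
    if total_charge < 1:
        raise ValueError("total_charge must be >= 1")
    if total_charge < f:
        raise ValueError("fewer charges than fixed charges")
    return (comp.mass() + (total_charge - f) * PROTON_MASS) / total_charge


def reporter_mz(tag: Modification) -> float:
    """m/z of a fixed-charge tag's reporter cation.

    The reporter composition is the intact cation's atoms (for TPP,
    protonated 2,4,6-triphenylpyridine C23H18N+), so the m/z is simply its
    composition mass divided by the reporter charge.
    """
    if tag.reporter is None or not tag.reporter:
        raise ValueError(f"tag {tag.name!r} has no reporter definition")
    return tag.reporter.mass() / tag.reporter_charge


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero — the convention of printed MRM lists."""
    import math

    factor = 10 ** ndigits
    return math.copysign(math.floor(round(abs(x) * factor, 6) + 0.5), x) / factor
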