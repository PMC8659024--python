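"""MRM transition-list construction, CSV round-trip and annotation.

A transition is a (precursor m/z, product m/z) pair monitored on a triple
quadrupole.  Lists are built for a peptide's modification *variants* — native,
Met-oxidized (``ox``), carbamidomethylated (``cam``), fixed-charge tagged
(``tpp``) and '+'-joined combinations — with the tag variant contributing the
tag's reporter ion as an extra confirmatory transition.  ``annotate_observed``
matches instrument transition lists back to theory within a tolerance,
accommodating the ≤0.1 m/z shifts of unit-resolution instrument-optimized
values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .chem import (
    BUILTIN_MODS,
    Modification,
    Peptide,
    fragment_mz,
    precursor_mz,
    reporter_mz,
)

__all__ = [
    "Transition",
    "TransitionList",
    "apply_variant",
    "build_transitions",
    "annotate_observed",
]

_ION_LABEL = re.compile(r"^(?:(?P<series>[by])(?P<index>\d+)|reporter)$")

VARIANT_MODS = {"ox": "Oxidation", "cam": "Carbamidomethyl", "tpp": "TPP"}


@dataclass(frozen=True)
class Transition:
    precursor_mz: float
    product_mz: float
    precursor_charge: int
    ion_label: str
    peptide_id: str
    variant: str

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0 or self.product_mz <= 0:
            raise ValueError("m/z values must be positive")
        if not _ION_LABEL.match(self.ion_label):
            raise ValueError(f"unparseable ion label {self.ion_label!r}")


class TransitionList:
    """Ordered, duplicate-free transition records plus provenance metadata."""

    def __init__(self, records: list[Transition], metadata: dict | None = None):
        seen = set()
        for rec in records:
            key = (rec.precursor_mz, rec.product_mz, rec.ion_label)
            if key in seen:
                raise ValueError(f"duplicate transition {key}")
            seen.add(key)
        self.records = list(records)
        self.metadata = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "peptide": r.peptide_id,
                    "variant": r.variant,
                    "precursor_mz": r.precursor_mz,
                    "precursor_charge": r.precursor_charge,
                    "product_mz": r.product_mz,
                    "ion_label": r.ion_label,
                }
                for r in self.records
            ],
            columns=[
                "peptide",
                "variant",
                "precursor_mz",
                "precursor_charge",
                "product_mz",
                "ion_label",
            ],
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df["precursor_mz"] = df["precursor_mz"].map(lambda v: f"{v:.4f}")
        df["product_mz"] = df["product_mz"].map(lambda v: f"{v:.4f}")
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TransitionList":
        df = pd.read_csv(path)
        records = [
            Transition(
                precursor_mz=float(row.precursor_mz),
                product_mz=float(row.product_mz),
                precursor_charge=int(row.precursor_charge),
                ion_label=str(row.ion_label),
                peptide_id=str(row.peptide),
                variant=str(row.variant),
            )
            for row in df.itertuples()
        ]
        return cls(records, metadata={"source": str(path)})


def apply_variant(sequence: str, variant: str, mods: dict[str, Modification] | None = None) -> Peptide:
    """Build the modified :class:`Peptide` for a variant label.

    ``variant`` is 'native' or a '+'-joined subset of {ox, cam, tpp}: ox puts
    oxidation on the first methionine, cam carbamidomethylates every cysteine,
    tpp places the fixed-charge tag on the C-terminal lysine.
    """
    registry = dict(BUILTIN_MODS)
    if mods:
        registry.update(mods)
    parts = [] if variant == "native" else variant.split("+")
    site_mods: list[tuple[int, Modification]] = []
    for part in parts:
        if part not in VARIANT_MODS:
            raise ValueError(f"unknown variant component {part!r}")
        mod = registry[VARIANT_MODS[part]]
        if part == "ox":
            idx = sequence.find("M")
            if idx < 0:
                raise ValueError("ox variant requires a methionine")
            site_mods.append((idx + 1, mod))
        elif part == "cam":
            if "C" not in sequence:
                raise ValueError("cam variant requires a cysteine")
            site_mods.extend((i + 1, mod) for i, ch in enumerate(sequence) if ch == "C")
        elif part == "tpp":
            if not sequence.endswith("K"):
                raise ValueError("TPP variant requires a C-terminal lysine")
            site_mods.append((len(sequence), mod))
    return Peptide(sequence, tuple(sorted(site_mods)))


def _canonical_variant(variant: str) -> str:
    if variant == "native":
        return variant
    order = {"ox": 0, "cam": 1, "tpp": 2}
    parts = sorted(set(variant.split("+")), key=lambda p: order.get(p, 99))
    return "+".join(parts)


def build_transitions(
    sequence: str,
    precursor_charges: set[int],
    series: tuple[str, ...] = ("y", "b"),
    variants: tuple[str, ...] = ("native",),
    top_n: int = 3,
    peptide_id: str | None = None,
) -> TransitionList:
    """Enumerate theoretical MRM transitions for each variant and charge.

    For each fragment series, the ``top_n`` longest fragments are kept
    (longer fragments are the more specific product ions); the tpp variant
    additionally contributes the tag reporter transition.  Product ions are
    singly charged — protonated, or carried by the fixed charge alone when the
    fragment contains the tag.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    records: list[Transition] = []
    pid = peptide_id or sequence
    for variant in variants:
        canon = _canonical_variant(variant)
        pep = apply_variant(sequence, canon)
        for z in sorted(precursor_charges):
            prec = precursor_mz(pep, z)
            for ser in series:
                indices = sorted(range(1, len(sequence)), reverse=True)[:top_n]
                for idx in indices:
                    records.append(
                        Transition(
                            precursor_mz=prec,
                            product_mz=fragment_mz(pep, ser, idx, 1),
                            precursor_charge=z,
                            ion_label=f"{ser}{idx}",
                            peptide_id=pid,
                            variant=canon,
                        )
                    )
            if "tpp" in canon.split("+"):
                tag = next(m for _, m in pep.mods if m.fixed_charge_delta > 0)
                records.append(
                    Transition(
                        precursor_mz=prec,
                        product_mz=reporter_mz(tag),
                        precursor_charge=z,
                        ion_label="reporter",
                        peptide_id=pid,
                        variant=canon,
                    )
                )
    return TransitionList(
        records,
        metadata={
            "peptide": pid,
            "charges": sorted(precursor_charges),
            "series": list(series),
            "variants": [_canonical_variant(v) for v in variants],
            "top_n": top_n,
        },
    )


def _theoretical_candidates(sequence: str, charges: set[int]) -> list[Transition]:
    variants = ["native"]
    if "M" in sequence:
        variants.append("ox")
    if "C" in sequence:
        variants.append("cam")
    if sequence.endswith("K"):
        variants.append("tpp")
        if "M" in sequence:
            variants.append("ox+tpp")
    tl = build_transitions(
        sequence,
        precursor_charges=charges,
        series=("y", "b"),
        variants=tuple(variants),
        top_n=len(sequence) - 1,
    )
    return tl.records


def annotate_observed(
    observed: TransitionList,
    sequence: str,
    tolerance_mz: float = 0.1,
    charges: set[int] = frozenset({1, 2}),
) -> pd.DataFrame:
    """Match observed transitions to the nearest theoretical ion.

    A match requires agreement within ``tolerance_mz`` on *both* the
    precursor and the product m/z, across every supported variant of the
    peptide.  Ties are broken by smallest combined absolute deviation, then by
    lower fragment index.  Returns a report with one row per observation;
    unmatched rows have ``matched == False``.
    """
    if tolerance_mz < 0:
        raise ValueError("tolerance must be >= 0")
    candidates = _theoretical_candidates(sequence, set(charges))
    rows = []
    for obs in observed:
        best = None
        for cand in candidates:
            dprec = abs(obs.precursor_mz - cand.precursor_mz)
            dprod = abs(obs.product_mz - cand.product_mz)
            if dprec <= tolerance_mz and dprod <= tolerance_mz:
                m = _ION_LABEL.match(cand.ion_label)
                idx = int(m.group("index")) if m.group("index") else 0
                key = (dprec + dprod, idx)
                if best is None or key < best[0]:
                    best = (key, cand, dprec, dprod)
        row = {
            "precursor_mz": obs.precursor_mz,
            "product_mz": obs.product_mz,
            "matched": best is not None,
            "variant": best[1].variant if best else None,
            "ion_label": best[1].ion_label if best else None,
            "theo_precursor_mz": best[1].precursor_mz if best else None,
            "theo_product_mz": best[1].product_mz if best else None,
            "d_precursor": best[2] if best else None,
            "d_product": best[3] if best else None,
        }
        rows.append(row)
    return pd.DataFrame(rows)
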