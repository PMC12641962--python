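"""Qualitative physicochemical change reports for missense substitutions.

For a substitution ref->alt the report states whether the mutant residue is
larger or smaller (Zamyatnin 1972 mean residue volumes), more or less
hydrophobic (Kyte-Doolittle hydropathy index), and how its net side-chain
charge class changes at physiological pH (Asp/Glu negative, Lys/Arg
positive, all others including His neutral).  Structurally notorious
introductions (proline, glycine) and charge gain/loss are flagged.

The property scales ship as JSON and can be overridden for alternative
conventions; comparisons are strict, so equal values report "similar".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

from .variants import AminoAcid

__all__ = [
    "ChargeClass",
    "Change",
    "ResidueProperties",
    "PropertyDelta",
    "load_residue_properties",
    "default_residue_properties",
    "delta",
    "report",
]


class ChargeClass(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NEUTRAL = "neutral"


class Change(str, Enum):
    INCREASE = "increase"
    DECREASE = "decrease"
    SIMILAR = "similar"


@dataclass(frozen=True)
class ResidueProperties:
    """Per-residue scales: volume (A^3), hydropathy, charge class."""

    volume: Mapping[str, float]
    hydropathy: Mapping[str, float]
    charge_class: Mapping[str, ChargeClass]

    def __post_init__(self) -> None:
        expected = {
            "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His",
            "Ile", "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp",
            "Tyr", "Val",
        }
        for name, table in (
            ("volume", self.volume),
            ("hydropathy", self.hydropathy),
            ("charge_class", self.charge_class),
        ):
            missing = expected - set(table)
            if missing:
                raise ValueError(f"{name} table missing residues: {sorted(missing)}")


def load_residue_properties(path: str | Path) -> ResidueProperties:
    """Load a ``{residue: {volume, hydropathy, charge_class}}`` JSON table."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    entries = {k: v for k, v in raw.items() if not k.startswith("_")}
    return ResidueProperties(
        volume={r: float(v["volume"]) for r, v in entries.items()},
        hydropathy={r: float(v["hydropathy"]) for r, v in entries.items()},
        charge_class={r: ChargeClass(v["charge_class"]) for r, v in entries.items()},
    )


def default_residue_properties() -> ResidueProperties:
    ref = resources.files("varprio.data").joinpath("residue_properties.json")
    with resources.as_file(ref) as path:
        return load_residue_properties(path)


_DEFAULT: Optional[ResidueProperties] = None


def _default() -> ResidueProperties:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = default_residue_properties()
    return _DEFAULT


@dataclass(frozen=True)
class PropertyDelta:
    """Qualitative size / charge / hydrophobicity change for ref->alt."""

    ref: AminoAcid
    alt: AminoAcid
    size_change: Change
    charge_change: tuple[ChargeClass, ChargeClass]
    hydrophobicity_change: Change
    flags: frozenset[str]

    @property
    def is_identity(self) -> bool:
        return self.ref == self.alt


def _direction(a: float, b: float) -> Change:
    if b > a:
        return Change.INCREASE
    if b < a:
        return Change.DECREASE
    return Change.SIMILAR


def delta(
    ref: AminoAcid,
    alt: AminoAcid,
    properties: Optional[ResidueProperties] = None,
) -> PropertyDelta:
    """Compute the property change report for a missense substitution.

    Stop tokens are rejected: a premature stop is a truncation, not a
    substitution with comparable side-chain properties.
    """
    if ref.is_stop or alt.is_stop:
        raise ValueError("property deltas are defined for residue substitutions only")
    props = properties or _default()
    size = _direction(props.volume[ref.code3], props.volume[alt.code3])
    hydro = _direction(props.hydropathy[ref.code3], props.hydropathy[alt.code3])
    charge = (props.charge_class[ref.code3], props.charge_class[alt.code3])
    flags: set[str] = set()
    if ref != alt:
        if alt.code3 == "Pro":
            flags.add("proline_introduced")
        if alt.code3 == "Gly":
            flags.add("glycine_introduced")
        if charge[0] is not ChargeClass.NEUTRAL and charge[1] is ChargeClass.NEUTRAL:
            flags.add("charge_lost")
        if charge[0] is ChargeClass.NEUTRAL and charge[1] is not ChargeClass.NEUTRAL:
            flags.add("charge_gained")
    return PropertyDelta(ref, alt, size, charge, hydro, frozenset(flags))


_ARROWS = {Change.INCREASE: "↑", Change.DECREASE: "↓"}
_FLAG_NOTES = {
    "proline_introduced": "Proline may induce structural changes (rigidity, helix disruption)",
    "glycine_introduced": "Glycine adds backbone flexibility",
    "charge_lost": "Loss of charge, possible salt bridge disruption",
    "charge_gained": "Gain of charge",
}


def report(d: PropertyDelta) -> str:
    """Deterministic one-line summary in arrow notation, mirroring the
    style of automated mutation reports (e.g. "↑ Size, Neutral → Positive,
    ↓ Hydrophobicity")."""
    if d.is_identity:
        return "no property change"
    parts: list[str] = []
    if d.size_change is not Change.SIMILAR:
        parts.append(f"{_ARROWS[d.size_change]} Size")
    if d.charge_change[0] is not d.charge_change[1]:
        parts.append(
            f"{d.charge_change[0].value.capitalize()} → "
            f"{d.charge_change[1].value.capitalize()}"
        )
    if d.hydrophobicity_change is not Change.SIMILAR:
        parts.append(f"{_ARROWS[d.hydrophobicity_change]} Hydrophobicity")
    for flag in ("proline_introduced", "glycine_introduced", "charge_lost"):
        if flag in d.flags:
            parts.append(_FLAG_NOTES[flag])
    return ", ".join(parts) if parts else "no property change"
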