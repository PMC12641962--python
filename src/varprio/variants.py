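"""Variant domain types and HGVS-style nomenclature parsing.

The variant catalogues this package consumes describe each germline change
twice: as a coding-DNA edit (``c.`` string, e.g. ``c.3264dup``) and as its
protein-level consequence (``p.`` string, e.g. ``p.Gln1089fs``).  Protein
strings use three-letter residue codes on the canonical BRCA2 numbering
(UniProt P51587, 3418 residues); parsing classifies each change as missense,
frameshift, or stop-gained, the three consequence classes the downstream
triage rubric distinguishes.

Only the small HGVS subset that appears in germline panel reports is
supported (substitution, dup, del, delins at the cDNA level; substitution,
``fs`` and ``Ter`` suffixes at the protein level).  Intronic, UTR and more
exotic edits are out of scope.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "AminoAcid",
    "Consequence",
    "ProteinChange",
    "CdnaEdit",
    "VariantRecord",
    "CohortSizes",
    "VariantTable",
    "HgvsParseError",
    "VariantTableError",
    "parse_protein_hgvs",
    "parse_cdna_hgvs",
    "read_variant_table",
    "read_cohort_sizes",
]


class HgvsParseError(ValueError):
    """Raised when a nomenclature string cannot be interpreted."""


class VariantTableError(ValueError):
    """Raised when a variant table file violates its schema."""


# Canonical residues plus the stop token; bijection code3 <-> code1.
_CODE3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}
_CODE1_TO_3 = {v: k for k, v in _CODE3_TO_1.items()}


@dataclass(frozen=True)
class AminoAcid:
    """One of the 20 canonical residues, or the stop token ``Ter``."""

    code3: str
    code1: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if self.code3 not in _CODE3_TO_1:
            raise HgvsParseError(f"unknown residue code: {self.code3!r}")
        object.__setattr__(self, "code1", _CODE3_TO_1[self.code3])

    @classmethod
    def from_code1(cls, code1: str) -> "AminoAcid":
        if code1 not in _CODE1_TO_3:
            raise HgvsParseError(f"unknown one-letter residue code: {code1!r}")
        return cls(_CODE1_TO_3[code1])

    @property
    def is_stop(self) -> bool:
        return self.code3 == "Ter"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code3


TER = AminoAcid("Ter")


class Consequence(str, Enum):
    MISSENSE = "missense"
    FRAMESHIFT = "frameshift"
    STOP_GAINED = "stop_gained"


@dataclass(frozen=True)
class ProteinChange:
    """A protein-level change at a 1-based residue position.

    Invariants: missense changes carry a non-stop ``alt``; stop-gained
    changes carry ``alt == Ter``; frameshifts carry no ``alt`` (any residue
    printed before ``fs`` is normalised away, so ``p.Val3079fs`` and
    ``p.Val3079Phefs`` denote the same change).
    """

    ref: AminoAcid
    position: int
    alt: Optional[AminoAcid]
    consequence: Consequence

    def __post_init__(self) -> None:
        if self.position < 1:
            raise HgvsParseError(f"non-positive residue position: {self.position}")
        if self.ref.is_stop:
            raise HgvsParseError("reference residue may not be the stop token")
        c = self.consequence
        if c is Consequence.MISSENSE and (self.alt is None or self.alt.is_stop):
            raise HgvsParseError("missense change requires a non-stop alt residue")
        if c is Consequence.STOP_GAINED and (self.alt is None or not self.alt.is_stop):
            raise HgvsParseError("stop-gained change requires alt == Ter")
        if c is Consequence.FRAMESHIFT and self.alt is not None:
            raise HgvsParseError("frameshift change carries no alt residue")

    def format(self) -> str:
        """Canonical ``p.`` string (frameshifts print a bare ``fs`` suffix)."""
        if self.consequence is Consequence.FRAMESHIFT:
            suffix = "fs"
        else:
            suffix = self.alt.code3  # type: ignore[union-attr]
        return f"p.{self.ref.code3}{self.position}{suffix}"


_PROTEIN_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Za-z]*)$")


def parse_protein_hgvs(text: str) -> ProteinChange:
    """Parse a protein HGVS string such as ``p.Gln1089fs`` or ``p.Glu2947Ter``.

    Surrounding parentheses, as printed in some reports, are tolerated.
    """
    cleaned = text.strip()
    if cleaned.startswith("(") and cleaned.endswith(")"):
        cleaned = cleaned[1:-1]
    m = _PROTEIN_RE.match(cleaned)
    if not m:
        raise HgvsParseError(f"malformed protein HGVS: {text!r}")
    ref_code, pos_str, suffix = m.groups()
    ref = AminoAcid(ref_code)  # raises on unknown code
    position = int(pos_str)
    if position < 1:
        raise HgvsParseError(f"non-positive position in {text!r}")
    if not suffix:
        raise HgvsParseError(f"missing change suffix in {text!r}")
    if suffix.endswith("fs"):
        inserted = suffix[:-2]
        if inserted:  # e.g. p.Val3079Phefs -- inserted residue is discarded
            AminoAcid(inserted)  # still validate the token
        return ProteinChange(ref, position, None, Consequence.FRAMESHIFT)
    alt = AminoAcid(suffix)
    if alt.is_stop:
        return ProteinChange(ref, position, alt, Consequence.STOP_GAINED)
    return ProteinChange(ref, position, alt, Consequence.MISSENSE)


class CdnaEditKind(str, Enum):
    SUB = "sub"
    DUP = "dup"
    DEL = "del"
    DELINS = "delins"


@dataclass(frozen=True)
class CdnaEdit:
    """A coding-DNA edit descriptor; positions are as printed, unvalidated."""

    positions: tuple[int, ...]
    edit_kind: CdnaEditKind


_CDNA_RE = re.compile(r"^c\.(\d+)(?:_(\d+))?(.+)$")


def parse_cdna_hgvs(text: str) -> CdnaEdit:
    """Parse a cDNA HGVS string (substitution, dup, del, delins)."""
    cleaned = text.strip()
    # Tolerate a transcript prefix, e.g. "NM_000059.4(BRCA2):c.3264dup".
    if ":" in cleaned:
        cleaned = cleaned.split(":", 1)[1]
    m = _CDNA_RE.match(cleaned)
    if not m:
        raise HgvsParseError(f"malformed cDNA HGVS: {text!r}")
    a, b, rest = m.groups()
    positions = (int(a),) if b is None else (int(a), int(b))
    if any(p < 1 for p in positions):
        raise HgvsParseError(f"non-positive coding position in {text!r}")
    if len(positions) == 2 and positions[0] > positions[1]:
        raise HgvsParseError(f"inverted position range in {text!r}")
    if re.fullmatch(r"[ACGT]+>[ACGT]+", rest):
        kind = CdnaEditKind.SUB
    elif rest.startswith("delins") and re.fullmatch(r"delins[ACGT]*", rest):
        kind = CdnaEditKind.DELINS
    elif re.fullmatch(r"del[ACGT]*", rest):
        kind = CdnaEditKind.DEL
    elif re.fullmatch(r"dup[ACGT]*", rest):
        kind = CdnaEditKind.DUP
    else:
        raise HgvsParseError(f"unsupported cDNA edit {rest!r} in {text!r}")
    return CdnaEdit(positions, kind)


@dataclass(frozen=True)
class VariantRecord:
    """One catalogued variant with nomenclature, carrier counts and labels."""

    hgvs_cdna: str
    protein_change: ProteinChange
    rsid: Optional[str]
    carriers_bc: int
    carriers_oc: int
    clinical_classification: str
    clinvar_aggregate: tuple[str, ...] = ()
    clinvar_review: str = ""

    @property
    def key(self) -> str:
        """Stable join key: rsID when present, else the cDNA string."""
        return self.rsid if self.rsid else self.hgvs_cdna

    @property
    def carriers_total(self) -> int:
        return self.carriers_bc + self.carriers_oc


@dataclass(frozen=True)
class CohortSizes:
    bc: int
    oc: int
    both: int

    @property
    def total(self) -> int:
        return self.bc + self.oc + self.both


DEFAULT_COHORT_SIZES = CohortSizes(bc=116, oc=19, both=5)


@dataclass
class VariantTable:
    """An ordered variant catalogue plus the cohort group sizes it refers to."""

    records: list[VariantRecord]
    cohort_sizes: CohortSizes = DEFAULT_COHORT_SIZES

    def __post_init__(self) -> None:
        keys = [r.key for r in self.records]
        dupes = {k for k in keys if keys.count(k) > 1}
        if dupes:
            raise VariantTableError(f"duplicate variant keys: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, key: str) -> VariantRecord:
        for r in self.records:
            if r.key == key:
                return r
        raise KeyError(key)

    @property
    def keys(self) -> list[str]:
        return [r.key for r in self.records]


_REQUIRED_COLUMNS = (
    "hgvs_cdna",
    "hgvs_protein",
    "rsid",
    "carriers_bc",
    "carriers_oc",
    "clinical_classification",
    "clinvar_aggregate",
    "clinvar_review",
)


def read_variant_table(
    path: str | Path,
    cohort_sizes: CohortSizes = DEFAULT_COHORT_SIZES,
) -> VariantTable:
    """Load a tab-separated variant catalogue.

    Required columns: hgvs_cdna, hgvs_protein, rsid (empty allowed),
    carriers_bc, carriers_oc, clinical_classification, clinvar_aggregate
    (semicolon-separated label set), clinvar_review.
    """
    records: list[VariantRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise VariantTableError(f"{path}: missing mandatory columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                protein = parse_protein_hgvs(row["hgvs_protein"])
                parse_cdna_hgvs(row["hgvs_cdna"])  # validate; kind kept as metadata
                labels = tuple(
                    s.strip() for s in (row["clinvar_aggregate"] or "").split(";") if s.strip()
                )
                rsid = (row["rsid"] or "").strip() or None
                rec = VariantRecord(
                    hgvs_cdna=row["hgvs_cdna"].strip(),
                    protein_change=protein,
                    rsid=rsid,
                    carriers_bc=int(row["carriers_bc"]),
                    carriers_oc=int(row["carriers_oc"]),
                    clinical_classification=row["clinical_classification"].strip(),
                    clinvar_aggregate=labels,
                    clinvar_review=(row["clinvar_review"] or "").strip(),
                )
            except (HgvsParseError, ValueError, KeyError) as exc:
                raise VariantTableError(f"{path}: row {lineno}: {exc}") from exc
            if rec.carriers_total < 1:
                raise VariantTableError(
                    f"{path}: row {lineno}: catalogued variant has no carriers"
                )
            records.append(rec)
    try:
        return VariantTable(records, cohort_sizes)
    except VariantTableError as exc:
        raise VariantTableError(f"{path}: {exc}") from exc


def read_cohort_sizes(path: str | Path) -> CohortSizes:
    """Read group sizes from a JSON config ``{"bc": .., "oc": .., "both": ..}``."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return CohortSizes(bc=int(raw["bc"]), oc=int(raw["oc"]), both=int(raw["both"]))
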