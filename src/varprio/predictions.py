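"""Integration of SIFT / PolyPhen-2 scores into categorical calls.

Scores are produced by external annotation (e.g. Ensembl VEP) and supplied
as data; this module only thresholds them.  A SIFT score <= 0.05 is called
deleterious and a PolyPhen-2 score >= 0.85 damaging (both cutoffs
inclusive and overridable).  Truncating and unannotated variants carry no
scores and yield ``unknown`` calls that contribute no evidence downstream.

The categorical labels printed by the annotators ("Possibly damaging",
"Benign", ...) are retained for display only; the triage rubric consumes
the threshold-derived calls exclusively.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional

__all__ = [
    "SiftCall",
    "PolyphenCall",
    "ThresholdConfig",
    "RawScores",
    "PredictionProfile",
    "PredictionLoadError",
    "read_predictions",
    "classify",
    "UNKNOWN_PROFILE",
]


class PredictionLoadError(ValueError):
    """Raised when a predictions table violates its schema."""


class SiftCall(str, Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"
    UNKNOWN = "unknown"


class PolyphenCall(str, Enum):
    DAMAGING = "damaging"
    NOT_DAMAGING = "not_damaging"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ThresholdConfig:
    """Deleteriousness cutoffs: SIFT <= sift_cutoff, PolyPhen >= polyphen_cutoff."""

    sift_cutoff: float = 0.05
    polyphen_cutoff: float = 0.85

    def __post_init__(self) -> None:
        for name, v in (("sift_cutoff", self.sift_cutoff),
                        ("polyphen_cutoff", self.polyphen_cutoff)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


DEFAULT_THRESHOLDS = ThresholdConfig()


@dataclass(frozen=True)
class RawScores:
    """Raw predictor scores (absent = None) plus display labels."""

    sift_score: Optional[float] = None
    polyphen_score: Optional[float] = None
    sift_label: str = ""
    polyphen_label: str = ""


@dataclass(frozen=True)
class PredictionProfile:
    sift_score: Optional[float]
    polyphen_score: Optional[float]
    sift_call: SiftCall
    polyphen_call: PolyphenCall
    sift_label: str = ""
    polyphen_label: str = ""

    @property
    def concordant(self) -> bool:
        """Both predictors adverse."""
        return (
            self.sift_call is SiftCall.DELETERIOUS
            and self.polyphen_call is PolyphenCall.DAMAGING
        )

    @property
    def single_evidence(self) -> bool:
        """Exactly one predictor adverse."""
        return (self.sift_call is SiftCall.DELETERIOUS) ^ (
            self.polyphen_call is PolyphenCall.DAMAGING
        )


UNKNOWN_PROFILE = PredictionProfile(None, None, SiftCall.UNKNOWN, PolyphenCall.UNKNOWN)


def _parse_score(cell: Optional[str], column: str, where: str) -> Optional[float]:
    text = (cell or "").strip()
    if not text:
        return None
    try:
        value = float(text)
    except ValueError as exc:
        raise PredictionLoadError(f"{where}: non-numeric {column} {text!r}") from exc
    if not (0.0 <= value <= 1.0):
        raise PredictionLoadError(f"{where}: {column} {value} outside [0, 1]")
    return value


def read_predictions(path: str | Path) -> dict[str, RawScores]:
    """Load a predictions TSV keyed by variant key.

    Required columns: variant_key, sift_score, polyphen_score (empty cell =
    score absent).  Optional display columns: sift_label, polyphen_label.
    Keys not present in any variant table are retained for a later join.
    """
    scores: dict[str, RawScores] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in ("variant_key", "sift_score", "polyphen_score"):
            if col not in header:
                raise PredictionLoadError(f"{path}: missing mandatory column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            key = (row.get("variant_key") or "").strip()
            if not key:
                raise PredictionLoadError(f"{path}: row {lineno}: empty variant_key")
            if key in scores:
                raise PredictionLoadError(f"{path}: row {lineno}: duplicate key {key!r}")
            where = f"{path}: row {lineno}"
            scores[key] = RawScores(
                sift_score=_parse_score(row.get("sift_score"), "sift_score", where),
                polyphen_score=_parse_score(
                    row.get("polyphen_score"), "polyphen_score", where
                ),
                sift_label=(row.get("sift_label") or "").strip(),
                polyphen_label=(row.get("polyphen_label") or "").strip(),
            )
    return scores


def classify(
    scores: RawScores, thresholds: ThresholdConfig = DEFAULT_THRESHOLDS
) -> PredictionProfile:
    """Derive categorical calls from raw scores at the configured cutoffs."""
    if scores.sift_score is None:
        sift_call = SiftCall.UNKNOWN
    elif scores.sift_score <= thresholds.sift_cutoff:
        sift_call = SiftCall.DELETERIOUS
    else:
        sift_call = SiftCall.TOLERATED
    if scores.polyphen_score is None:
        polyphen_call = PolyphenCall.UNKNOWN
    elif scores.polyphen_score >= thresholds.polyphen_cutoff:
        polyphen_call = PolyphenCall.DAMAGING
    else:
        polyphen_call = PolyphenCall.NOT_DAMAGING
    return PredictionProfile(
        sift_score=scores.sift_score,
        polyphen_score=scores.polyphen_score,
        sift_call=sift_call,
        polyphen_call=polyphen_call,
        sift_label=scores.sift_label,
        polyphen_label=scores.polyphen_label,
    )
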