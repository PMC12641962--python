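"""Mapping of protein residue positions onto annotated functional domains.

BRCA2 variant interpretation leans heavily on where a substitution falls:
the eight RAD51-binding BRC repeats (residues 1003-2082), the DNA-binding
domain (2804-3054), its C-terminal portion known as the terminal DBD
(3052-3185), and the C-terminal region beyond 3190.  Intervals are closed
and 1-based; any interval set can be supplied via JSON config so the mapper
generalizes to other proteins.

A position is *inside* a domain when start <= position <= end (overlaps are
broken by smallest interval span, then file order), *boundary* when it lies
in a gap but within ``boundary_window`` residues of some interval edge, and
*outside* otherwise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from .variants import VariantTable

__all__ = [
    "DomainAnnotation",
    "DomainCategory",
    "DomainAssignment",
    "DomainConfigError",
    "load_domain_config",
    "default_domain_config",
    "map_position",
    "assign_all",
    "DEFAULT_BOUNDARY_WINDOW",
]

DEFAULT_BOUNDARY_WINDOW = 5


class DomainConfigError(ValueError):
    """Raised for malformed domain interval configs."""


@dataclass(frozen=True)
class DomainAnnotation:
    """A named closed residue interval, optionally flagged as critical.

    ``critical`` marks domains whose disruption the triage rubric treats as
    escalating evidence (for BRCA2: BRC repeats, DBD, terminal DBD).
    """

    name: str
    start: int
    end: int
    critical: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise DomainConfigError(
                f"domain {self.name!r}: invalid interval {self.start}-{self.end}"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def gap_distance(self, position: int) -> int:
        """Residue distance to the interval (0 when inside)."""
        if position < self.start:
            return self.start - position
        if position > self.end:
            return position - self.end
        return 0


class DomainCategory(str, Enum):
    INSIDE = "inside"
    BOUNDARY = "boundary"
    OUTSIDE = "outside"


@dataclass(frozen=True)
class DomainAssignment:
    domain: Optional[DomainAnnotation]
    category: DomainCategory
    distance_to_nearest: float  # residues; 0 when inside, inf with no domains

    @property
    def in_critical_domain(self) -> bool:
        return (
            self.category is DomainCategory.INSIDE
            and self.domain is not None
            and self.domain.critical
        )


def _validate(domains: Sequence[DomainAnnotation]) -> tuple[DomainAnnotation, ...]:
    names = [d.name for d in domains]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise DomainConfigError(f"duplicate domain names: {sorted(dupes)}")
    return tuple(domains)


def load_domain_config(path: str | Path) -> tuple[tuple[DomainAnnotation, ...], int]:
    """Load ``(domains, boundary_window)`` from a JSON config file.

    Format: ``{"boundary_window": int, "domains": [{"name", "start", "end",
    "critical"}, ...]}``; a bare list of domain objects is also accepted.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    if isinstance(raw, list):
        entries, window = raw, DEFAULT_BOUNDARY_WINDOW
    else:
        entries = raw.get("domains", [])
        window = int(raw.get("boundary_window", DEFAULT_BOUNDARY_WINDOW))
    if window < 0:
        raise DomainConfigError(f"boundary_window must be >= 0, got {window}")
    domains = _validate(
        [
            DomainAnnotation(
                name=str(e["name"]),
                start=int(e["start"]),
                end=int(e["end"]),
                critical=bool(e.get("critical", False)),
            )
            for e in entries
        ]
    )
    return domains, window


def default_domain_config() -> tuple[tuple[DomainAnnotation, ...], int]:
    """The packaged BRCA2 interval set (UniProt P51587 numbering)."""
    ref = resources.files("varprio.data").joinpath("brca2_domains.json")
    with resources.as_file(ref) as path:
        return load_domain_config(path)


def map_position(
    position: int,
    domains: Sequence[DomainAnnotation],
    boundary_window: int = DEFAULT_BOUNDARY_WINDOW,
) -> DomainAssignment:
    """Assign a residue position to inside / boundary / outside.

    Total and deterministic: overlapping intervals are broken by smallest
    span then input order; the boundary category credits positions falling
    in an annotation gap to their nearest interval edge.
    """
    if position < 1:
        raise ValueError(f"residue positions are 1-based, got {position}")
    if boundary_window < 0:
        raise ValueError("boundary_window must be >= 0")
    containing = [(d.span, i, d) for i, d in enumerate(domains) if d.contains(position)]
    if containing:
        _, _, winner = min(containing, key=lambda t: (t[0], t[1]))
        return DomainAssignment(winner, DomainCategory.INSIDE, 0)
    if not domains:
        return DomainAssignment(None, DomainCategory.OUTSIDE, math.inf)
    dist, _, nearest = min(
        (d.gap_distance(position), i, d) for i, d in enumerate(domains)
    )
    if dist <= boundary_window:
        return DomainAssignment(nearest, DomainCategory.BOUNDARY, dist)
    return DomainAssignment(None, DomainCategory.OUTSIDE, dist)


def assign_all(
    table: VariantTable,
    domains: Sequence[DomainAnnotation],
    boundary_window: int = DEFAULT_BOUNDARY_WINDOW,
) -> dict[str, DomainAssignment]:
    """Map every catalogued variant; returns a dict keyed by variant key."""
    return {
        rec.key: map_position(rec.protein_change.position, domains, boundary_window)
        for rec in table
    }
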