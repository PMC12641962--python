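"""Exact-test comparison of carrier counts against reference populations.

A cohort's per-variant carrier count (k1 carriers out of n1 patients) is
compared with a reference count (k2 out of n2 — another cohort's carriers,
or a database's allele count out of its allele number).  The comparison is
the two-sided Fisher exact test: conditional on the margins, the p-value
sums the hypergeometric point probabilities of every 2x2 table whose
probability does not exceed the observed table's (with a 1e-7 relative
tolerance absorbing floating-point ties).  Point probabilities are computed
in log space, so million-scale database denominators are handled exactly as
printed.

Note the deliberate unit mismatch mirrored from published comparisons:
cohort counts are carriers-per-patient while database counts are
alleles-per-allele-number.  The report carries a ``kind`` label so readers
can see which construction each row uses.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from scipy.special import gammaln

from .variants import VariantTable

__all__ = [
    "CountPair",
    "FreqComparison",
    "ReferenceCount",
    "CarrierFrequency",
    "fisher_two_sided",
    "read_references",
    "compare_table",
    "carrier_frequency",
    "format_p",
]

# Relative tolerance treating near-equal point probabilities as ties.
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class CountPair:
    """Counts for a 2x2 comparison: k carriers out of n in each group."""

    k1: int
    n1: int
    k2: int
    n2: int

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("group denominators must be >= 1")
        if not (0 <= self.k1 <= self.n1 and 0 <= self.k2 <= self.n2):
            raise ValueError("carrier counts must satisfy 0 <= k <= n")

    def swapped(self) -> "CountPair":
        return CountPair(self.k2, self.n2, self.k1, self.n1)


@dataclass(frozen=True)
class FreqComparison:
    counts: CountPair
    odds_ratio: float  # may be inf
    p_two_sided: float


def _log_hypergeom_pmf(k: np.ndarray, K: int, n1: int, N: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeom(N, K, n1)."""
    return (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(N - K + 1) - gammaln(n1 - k + 1) - gammaln(N - K - n1 + k + 1)
        - (gammaln(N + 1) - gammaln(n1 + 1) - gammaln(N - n1 + 1))
    )


def fisher_two_sided(counts: CountPair) -> FreqComparison:
    """Two-sided Fisher exact test on a 2x2 carrier-count table.

    Returns the comparison with the sample odds ratio
    ``(k1 (n2-k2)) / ((n1-k1) k2)`` (division by zero reported as inf) and
    a p-value guaranteed to lie in (0, 1].
    """
    k1, n1, k2, n2 = counts.k1, counts.n1, counts.k2, counts.n2
    N = n1 + n2
    K = k1 + k2
    lo = max(0, K - n2)
    hi = min(K, n1)
    support = np.arange(lo, hi + 1)
    logpmf = _log_hypergeom_pmf(support, K, n1, N)
    obs = logpmf[k1 - lo]
    included = logpmf <= obs + math.log1p(_TIE_RTOL)
    # log-sum-exp over the included tables
    m = logpmf[included].max()
    p = float(math.exp(m) * np.exp(logpmf[included] - m).sum())
    p = min(p, 1.0)
    p = max(p, 5e-324)

    num = k1 * (n2 - k2)
    den = (n1 - k1) * k2
    if den == 0:
        odds = math.inf if num > 0 else math.nan
    else:
        odds = num / den
    return FreqComparison(counts, odds, p)


@dataclass(frozen=True)
class ReferenceCount:
    variant_key: str
    source_label: str
    k2: int
    n2: int
    kind: str  # "cohort" (carriers/patients) or "database" (alleles/alleles)


def read_references(path: str | Path) -> list[ReferenceCount]:
    """Load reference counts from a TSV with columns
    variant_key, source_label, k2, n2, kind."""
    rows: list[ReferenceCount] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in ("variant_key", "source_label", "k2", "n2", "kind"):
            if col not in header:
                raise ValueError(f"{path}: missing mandatory column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            kind = (row["kind"] or "").strip()
            if kind not in ("cohort", "database"):
                raise ValueError(f"{path}: row {lineno}: unknown kind {kind!r}")
            rows.append(
                ReferenceCount(
                    variant_key=row["variant_key"].strip(),
                    source_label=row["source_label"].strip(),
                    k2=int(row["k2"]),
                    n2=int(row["n2"]),
                    kind=kind,
                )
            )
    return rows


@dataclass(frozen=True)
class ComparisonRow:
    variant_key: str
    source_label: str
    kind: str
    comparison: FreqComparison


def compare_table(
    table: VariantTable, references: Iterable[ReferenceCount]
) -> list[ComparisonRow]:
    """One Fisher comparison per (variant, reference) pair.

    The cohort side is the variant's total carriers out of the full cohort
    size; reference rows whose key matches no catalogued variant are
    skipped with a warning.
    """
    n1 = table.cohort_sizes.total
    by_key = {rec.key: rec for rec in table}
    out: list[ComparisonRow] = []
    for ref in references:
        rec = by_key.get(ref.variant_key)
        if rec is None:
            warnings.warn(
                f"reference row for unknown variant key {ref.variant_key!r} skipped",
                stacklevel=2,
            )
            continue
        counts = CountPair(rec.carriers_total, n1, ref.k2, ref.n2)
        out.append(
            ComparisonRow(ref.variant_key, ref.source_label, ref.kind, fisher_two_sided(counts))
        )
    return out


@dataclass(frozen=True)
class CarrierFrequency:
    numerator: int
    denominator: int

    @property
    def proportion(self) -> float:
        return self.numerator / self.denominator

    @property
    def percent(self) -> float:
        """Percentage rounded to 2 decimals."""
        return round(100.0 * self.proportion, 2)


def carrier_frequency(table: VariantTable, group: str = "all") -> CarrierFrequency:
    """Cohort carrier frequency for ``group`` in {"BC", "OC", "all"}."""
    sizes = table.cohort_sizes
    g = group.upper() if group.lower() != "all" else "all"
    if g == "BC":
        num, den = sum(r.carriers_bc for r in table), sizes.bc
    elif g == "OC":
        num, den = sum(r.carriers_oc for r in table), sizes.oc
    elif g == "all":
        num, den = sum(r.carriers_total for r in table), sizes.total
    else:
        raise ValueError(f"unknown group {group!r}; expected BC, OC or all")
    if den == 0:
        raise ValueError(f"group {group!r} has zero denominator")
    return CarrierFrequency(num, den)


def format_p(p: float) -> str:
    """Display format: 4 decimal places; tiny values shown as '<0.0001'."""
    if p < 0.00005:
        return "<0.0001"
    return f"{p:.4f}"
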