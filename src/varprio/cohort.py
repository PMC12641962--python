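"""Descriptive cohort summaries and carrier vs non-carrier comparisons.

Patients are held in a pandas DataFrame, one row per patient, with a
``group`` column (BC / OC / BC+OC), a boolean ``carrier`` column, numeric
columns (age, age at menarche) and closed-vocabulary categorical columns.
``summarize`` produces the per-group descriptive tables (counts, %, mean
+/- SD, range); ``compare_by_carrier`` tests one variable between carriers
and non-carriers within a diagnosis group — Fisher exact on the 2x2 for
categorical variables (sharing the single exact-test implementation in
:mod:`varprio.frequency`), Welch's unequal-variance t-test for continuous
ones.  Displayed proportions are rounded half-up to whole percent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import pandas as pd
from scipy import stats

from .frequency import CountPair, fisher_two_sided

__all__ = [
    "CohortSummary",
    "GroupComparison",
    "summarize",
    "compare_by_carrier",
    "PATIENT_COLUMNS",
]

PATIENT_COLUMNS = (
    "group", "carrier", "age", "age_menarche", "bmi_class", "alcohol",
    "tobacco", "hormones", "menopause", "abortion", "breastfeeding",
    "family_history", "detection", "laterality", "stage", "histology",
    "subtype", "ki67_class", "lymph_node", "chemo_response",
)

_CONTINUOUS = ("age", "age_menarche")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class CohortSummary:
    """Per-group descriptives: one frame for continuous, one for categorical."""

    continuous: pd.DataFrame  # variable, group, n, mean, sd, min, max, sd_undefined
    categorical: pd.DataFrame  # variable, level, group, n, pct


def summarize(patients: pd.DataFrame) -> CohortSummary:
    """Descriptive table per diagnosis group.

    Groups with no patients are omitted with a warning.  A single-patient
    group reports SD as 0 with ``sd_undefined`` flagged.  Percentages of an
    exhaustive categorical sum to 100 within rounding.
    """
    if patients.empty:
        raise ValueError("patient table is empty")
    cont_rows, cat_rows = [], []
    for group, sub in patients.groupby("group", sort=True):
        if sub.empty:  # pragma: no cover - groupby drops empty levels
            warnings.warn(f"group {group!r} has no patients; omitted", stacklevel=2)
            continue
        for var in _CONTINUOUS:
            if var not in sub.columns:
                continue
            vals = sub[var].dropna()
            undefined = len(vals) < 2
            cont_rows.append(
                {
                    "variable": var,
                    "group": group,
                    "n": len(vals),
                    "mean": float(vals.mean()),
                    "sd": 0.0 if undefined else float(vals.std(ddof=1)),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "sd_undefined": undefined,
                }
            )
        for var in patients.columns:
            if var in _CONTINUOUS or var in ("group",):
                continue
            counts = sub[var].value_counts(dropna=False).sort_index()
            total = int(counts.sum())
            for level, n in counts.items():
                cat_rows.append(
                    {
                        "variable": var,
                        "level": level,
                        "group": group,
                        "n": int(n),
                        "pct": _round_half_up(100.0 * n / total),
                    }
                )
    return CohortSummary(pd.DataFrame(cont_rows), pd.DataFrame(cat_rows))


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    level: Optional[object]  # categorical level tested (None for continuous)
    carrier_n: int
    noncarrier_n: int
    carrier_stat: float  # count (categorical) or mean (continuous)
    noncarrier_stat: float
    carrier_pct: Optional[int]  # rounded proportions; None for continuous
    noncarrier_pct: Optional[int]
    test: str  # "fisher_exact" or "welch_t"
    p_two_sided: float


def compare_by_carrier(
    patients: pd.DataFrame,
    variable: str,
    level: Optional[object] = None,
    group: Optional[str] = None,
) -> GroupComparison:
    """Compare one variable between carriers and non-carriers.

    For categorical variables, ``level`` names the category tested
    (defaults to ``True`` for boolean columns); the test is two-sided
    Fisher exact on the resulting 2x2.  For continuous variables the test
    is Welch's t.  ``group`` restricts the comparison to one diagnosis
    group, as stratified case tables do.
    """
    sub = patients if group is None else patients[patients["group"] == group]
    carriers = sub[sub["carrier"]]
    noncarriers = sub[~sub["carrier"]]
    if carriers.empty or noncarriers.empty:
        raise ValueError("both carrier strata must be non-empty")

    if variable in _CONTINUOUS or pd.api.types.is_float_dtype(sub[variable]):
        a = carriers[variable].dropna()
        b = noncarriers[variable].dropna()
        if a.nunique() <= 1 and b.nunique() <= 1 and set(a.unique()) == set(b.unique()):
            p = 1.0  # degenerate: all values identical in both strata
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        return GroupComparison(
            variable, None, len(a), len(b),
            float(a.mean()), float(b.mean()), None, None, "welch_t", p,
        )

    if level is None:
        if pd.api.types.is_bool_dtype(sub[variable]):
            level = True
        else:
            raise ValueError(
                f"variable {variable!r} is categorical; a level must be given"
            )
    k1 = int((carriers[variable] == level).sum())
    k2 = int((noncarriers[variable] == level).sum())
    n1, n2 = len(carriers), len(noncarriers)
    p = fisher_two_sided(CountPair(k1, n1, k2, n2)).p_two_sided
    return GroupComparison(
        variable, level, n1, n2, float(k1), float(k2),
        _round_half_up(100.0 * k1 / n1), _round_half_up(100.0 * k2 / n2),
        "fisher_exact", p,
    )
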