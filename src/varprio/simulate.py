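"""Synthetic cohorts and variant panels with the structure the analysis assumes.

The patient-level data behind published hereditary-cancer cohort tables is
rarely deposited; this module generates stand-in cohorts whose stratified
margins match the published summary statistics, so that every analysis
stage (descriptives, carrier comparisons, prioritization, frequency tests)
can be exercised end-to-end without any download.

Two sampling modes are provided.  The default ``quota`` mode allocates
carrier status and categorical covariate levels by largest-remainder
rounding of the stratum probabilities and shuffles the assignment order:
generated cohorts then reproduce the published stratified counts exactly
(up to integer rounding), which makes parameter-recovery checks meaningful
at any cohort size.  The ``bernoulli`` mode draws every patient i.i.d. and
emulates genuine sampling variation.  Ages are always drawn from truncated
normals.  All randomness is seeded; identical spec + seed gives
byte-identical output.

Defaults encode a two-arm breast/ovarian cancer cohort of 140 patients
(116 BC / 19 OC / 5 with both), carrier prevalence 14/116, 4/19 and 0/5,
group age means 46.9, 56.6 and 49.0 years, and carrier-associated shifts
for overweight, family history, chemotherapy response, bilaterality and
abortion history matching the published carrier-stratum proportions.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .predictions import RawScores
from .rubric import ClinvarEvidence
from .variants import (
    AminoAcid,
    CohortSizes,
    Consequence,
    ProteinChange,
    VariantRecord,
    VariantTable,
)

__all__ = [
    "CohortSpec",
    "PanelSpec",
    "SpecError",
    "default_cohort_spec",
    "default_panel_spec",
    "generate_cohort",
    "generate_panel",
    "write_cohort",
    "write_panel",
]

GROUPS = ("BC", "OC", "BC+OC")


class SpecError(ValueError):
    """Raised for invalid generator specifications."""


def _shifted(
    marginal: Mapping[object, float],
    level: object,
    p_carrier: float,
    p_noncarrier: float,
) -> dict[str, dict[object, float]]:
    """Per-stratum level probabilities: pin ``level`` to the stratum value
    and redistribute the remaining mass over the other levels in proportion
    to their marginal shares."""
    others = {k: v for k, v in marginal.items() if k != level}
    rest = sum(others.values())
    out: dict[str, dict[object, float]] = {}
    for stratum, p in (("carrier", p_carrier), ("noncarrier", p_noncarrier)):
        probs = {level: p}
        for k, v in others.items():
            probs[k] = (1.0 - p) * (v / rest if rest > 0 else 1.0 / len(others))
        out[stratum] = probs
    return out


def _bool(p: float) -> dict[object, float]:
    return {True: p, False: 1.0 - p}


def _bool_shifted(p_carrier: float, p_noncarrier: float) -> dict[str, dict[object, float]]:
    return {"carrier": _bool(p_carrier), "noncarrier": _bool(p_noncarrier)}


def _default_categorical() -> dict[str, dict[str, dict]]:
    """variable -> group -> either {level: p} (both strata) or
    {"carrier": {...}, "noncarrier": {...}}."""
    bmi_bc = {"normal": 0.76, "overweight": 0.17, "obese": 0.07}
    bmi_oc = {"normal": 0.58, "overweight": 0.26, "obese": 0.16}
    fam_bc = {"first_degree": 0.64, "other": 0.14, "none": 0.22}
    fam_oc = {"first_degree": 13 / 19, "other": 3 / 19, "none": 3 / 19}
    chemo_bc = {"complete": 0.63, "partial": 0.29, "no_response": 0.03, "recurrence": 0.05}
    chemo_oc = {"complete": 0.42, "partial": 0.42, "no_response": 0.05, "recurrence": 0.11}
    return {
        "bmi_class": {
            "BC": _shifted(bmi_bc, "overweight", 4 / 14, 6 / 102),
            "OC": _shifted(bmi_oc, "overweight", 2 / 4, 2 / 15),
            "BC+OC": {"obese": 1.0},
        },
        "alcohol": {"BC": _bool(0.16), "OC": _bool(0.26), "BC+OC": _bool(0.0)},
        "tobacco": {"BC": _bool(0.15), "OC": _bool(0.16), "BC+OC": _bool(0.0)},
        "hormones": {"BC": _bool(0.35), "OC": _bool(0.0), "BC+OC": _bool(0.2)},
        "menopause": {"BC": _bool(0.47), "OC": _bool(0.84), "BC+OC": _bool(0.6)},
        "abortion": {
            "BC": _bool(0.16),
            "OC": _bool_shifted(0.0, 12 / 15),
            "BC+OC": _bool(0.0),
        },
        "breastfeeding": {"BC": _bool(0.69), "OC": _bool(0.74), "BC+OC": _bool(0.6)},
        "family_history": {
            "BC": _shifted(fam_bc, "first_degree", 14 / 14, 58 / 102),
            "OC": _shifted(fam_oc, "first_degree", 2 / 4, 9 / 15),
            "BC+OC": {"first_degree": 0.6, "other": 0.2, "none": 0.2},
        },
        "detection": {
            "BC": {"autodetection": 0.92, "imaging": 0.08},
            "OC": {"imaging": 1.0},
            "BC+OC": {"imaging": 1.0},
        },
        "laterality": {
            "BC": {"unilateral": 0.90, "bilateral": 0.10},
            "OC": _shifted(
                {"unilateral": 0.89, "bilateral": 0.11}, "bilateral", 3 / 4, 2 / 15
            ),
            "BC+OC": {"unilateral": 1.0},
        },
        "stage": {
            "BC": {"in_situ": 0.03, "I": 0.16, "II": 0.31, "III": 0.37, "IV": 0.13},
            "OC": {"I": 0.10, "II": 0.32, "III": 0.37, "IV": 0.21},
            "BC+OC": {"II": 0.6, "III": 0.4},
        },
        "histology": {
            "BC": {"ductal": 0.94, "lobular": 0.05, "mixed": 0.01},
            "OC": {"high_grade_serous": 1.0},
            "BC+OC": {"ductal_serous": 1.0},
        },
        "subtype": {
            "BC": {
                "luminal_a": 0.20,
                "luminal_b": 0.26,
                "triple_negative": 0.44,
                "luminal_ab": 0.03,
                "tn_luminal_a": 0.07,
            },
            "OC": {"high_grade_serous": 1.0},
            "BC+OC": {"serous_tn": 0.6, "serous_luminal_a": 0.4},
        },
        "ki67_class": {
            "BC": {"lt20": 0.18, "ge20": 0.82},
            "OC": {"ge20": 1.0},
            "BC+OC": {"lt20": 0.2, "ge20": 0.8},
        },
        "lymph_node": {"BC": _bool(0.40), "OC": _bool(0.21), "BC+OC": _bool(0.0)},
        "chemo_response": {
            "BC": _shifted(chemo_bc, "complete", 5 / 14, 70 / 102),
            "OC": _shifted(chemo_oc, "complete", 1 / 4, 3 / 15),
            "BC+OC": {"complete": 0.8, "recurrence": 0.2},
        },
    }


@dataclass
class CohortSpec:
    """Full parameterization of the synthetic two-arm cohort."""

    sizes: dict[str, int] = field(
        default_factory=lambda: {"BC": 116, "OC": 19, "BC+OC": 5}
    )
    carrier_prevalence: dict[str, float] = field(
        default_factory=lambda: {"BC": 14 / 116, "OC": 4 / 19, "BC+OC": 0.0}
    )
    age: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "BC": (46.9, 13.3),
            "OC": (56.6, 11.1),
            "BC+OC": (49.0, 10.7),
        }
    )
    age_menarche: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "BC": (12.2, 1.56),
            "OC": (11.8, 0.89),
            "BC+OC": (12.4, 0.54),
        }
    )
    age_bounds: tuple[float, float] = (18.0, 95.0)
    menarche_bounds: tuple[float, float] = (8.0, 16.0)
    categorical: dict[str, dict[str, dict]] = field(default_factory=_default_categorical)
    allocation: str = "quota"  # "quota" reproduces stratum margins exactly
    seed: int = 0

    def validate(self) -> None:
        if self.allocation not in ("quota", "bernoulli"):
            raise SpecError(f"unknown allocation mode {self.allocation!r}")
        for g, n in self.sizes.items():
            if n < 0:
                raise SpecError(f"negative group size for {g!r}")
        for g, p in self.carrier_prevalence.items():
            if not (0.0 <= p <= 1.0):
                raise SpecError(f"carrier prevalence for {g!r} outside [0, 1]: {p}")
        for var, per_group in self.categorical.items():
            for g, probs in per_group.items():
                strata = (
                    probs.values()
                    if set(probs) == {"carrier", "noncarrier"}
                    else [probs]
                )
                for stratum in strata:
                    vals = list(stratum.values())
                    if any(not (0.0 <= v <= 1.0) for v in vals):
                        raise SpecError(f"{var}/{g}: probability outside [0, 1]")
                    if abs(sum(vals) - 1.0) > 1e-9:
                        raise SpecError(f"{var}/{g}: probabilities sum to {sum(vals)}")

    def with_total(self, total: int) -> "CohortSpec":
        """Same structure at a different cohort size (groups scaled
        proportionally, largest remainder)."""
        base_total = sum(self.sizes.values())
        sizes = _largest_remainder(
            {g: total * n / base_total for g, n in self.sizes.items()}
        )
        return replace(self, sizes=sizes, categorical=copy.deepcopy(self.categorical))


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    return CohortSpec(seed=seed)


def _largest_remainder(targets: Mapping[object, float]) -> dict[object, int]:
    """Integer allocation matching ``targets`` totals by largest remainder."""
    floors = {k: int(math.floor(v)) for k, v in targets.items()}
    total = round(sum(targets.values()))
    shortfall = total - sum(floors.values())
    remainders = sorted(
        targets, key=lambda k: (targets[k] - floors[k]), reverse=True
    )
    for k in remainders[:shortfall]:
        floors[k] += 1
    return floors


def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, bounds: tuple[float, float]
) -> np.ndarray:
    lo, hi = bounds
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _draw_levels(
    rng: np.random.Generator,
    n: int,
    probs: Mapping[object, float],
    allocation: str,
) -> np.ndarray:
    levels = list(probs.keys())
    p = np.array([probs[l] for l in levels], dtype=float)
    if n == 0:
        return np.empty(0, dtype=object)
    if allocation == "bernoulli":
        idx = rng.choice(len(levels), size=n, p=p / p.sum())
    else:
        counts = _largest_remainder({i: n * pi for i, pi in enumerate(p / p.sum())})
        idx = np.repeat(
            np.array(sorted(counts), dtype=int),
            np.array([counts[i] for i in sorted(counts)], dtype=int),
        )
        idx = rng.permutation(idx)
    out = np.empty(n, dtype=object)
    for i, lvl in enumerate(levels):
        out[idx == i] = lvl
    return out


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate the synthetic patient table (one row per patient).

    Deterministic given ``spec.seed``; ages truncated to ``age_bounds``;
    carrier-associated covariates drawn from their per-stratum
    probabilities, everything else from group marginals.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    frames: list[pd.DataFrame] = []
    for group in GROUPS:
        n = spec.sizes.get(group, 0)
        if n == 0:
            continue
        carrier = _draw_levels(
            rng, n, _bool(spec.carrier_prevalence.get(group, 0.0)), spec.allocation
        ).astype(bool)
        df = pd.DataFrame({"group": [group] * n, "carrier": carrier})
        mean, sd = spec.age[group]
        df["age"] = np.round(_truncated_normal(rng, n, mean, sd, spec.age_bounds), 1)
        m_mean, m_sd = spec.age_menarche[group]
        df["age_menarche"] = np.round(
            _truncated_normal(rng, n, m_mean, m_sd, spec.menarche_bounds), 1
        )
        for var, per_group in spec.categorical.items():
            probs = per_group.get(group)
            if probs is None:
                df[var] = None
                continue
            values = np.empty(n, dtype=object)
            if set(probs) == {"carrier", "noncarrier"}:
                for stratum, mask in (("carrier", carrier), ("noncarrier", ~carrier)):
                    values[mask] = _draw_levels(
                        rng, int(mask.sum()), probs[stratum], spec.allocation
                    )
            else:
                values[:] = _draw_levels(rng, n, probs, spec.allocation)
            df[var] = values
        frames.append(df)
    if not frames:
        cols = ["group", "carrier", "age", "age_menarche"] + list(spec.categorical)
        return pd.DataFrame(columns=cols)
    out = pd.concat(frames, ignore_index=True)
    for var in ("alcohol", "tobacco", "hormones", "menopause", "abortion",
                "breastfeeding", "lymph_node"):
        if var in out.columns:
            out[var] = out[var].astype(bool)
    return out


# ---------------------------------------------------------------------------
# Variant panel generation


@dataclass
class PanelSpec:
    """Parameterization of a synthetic variant panel (catalogue + scores)."""

    n_variants: int = 13
    consequence_mix: dict[str, float] = field(
        default_factory=lambda: {
            "missense": 7 / 13,
            "frameshift": 5 / 13,
            "stop_gained": 1 / 13,
        }
    )
    position_range: tuple[int, int] = (1, 3418)
    score_adverse_weight: float = 0.5  # per-predictor probability of an adverse draw
    p_scores_available: float = 0.85  # fraction of missense variants with scores
    p_has_rsid: float = 0.8
    clinvar_label_probs: dict[str, float] = field(
        default_factory=lambda: {
            "Pathogenic": 0.20,
            "Likely pathogenic": 0.10,
            "Uncertain significance": 0.45,
            "Likely benign": 0.20,
            "Benign": 0.05,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_variants < 0:
            raise SpecError("n_variants must be >= 0")
        lo, hi = self.position_range
        if not (1 <= lo <= hi):
            raise SpecError(f"invalid position range {self.position_range}")
        if self.n_variants > hi - lo + 1:
            raise SpecError("n_variants exceeds the number of distinct positions")
        for name, probs in (
            ("consequence_mix", self.consequence_mix),
            ("clinvar_label_probs", self.clinvar_label_probs),
        ):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise SpecError(f"{name} weights must sum to 1")
        for p in (self.score_adverse_weight, self.p_scores_available, self.p_has_rsid):
            if not (0.0 <= p <= 1.0):
                raise SpecError("panel probabilities must lie in [0, 1]")


def default_panel_spec(seed: int = 0, n_variants: int = 13) -> PanelSpec:
    return PanelSpec(n_variants=n_variants, seed=seed)


_RESIDUES = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)
_BASES = "ACGT"


def generate_panel(
    spec: PanelSpec,
) -> tuple[VariantTable, dict[str, RawScores], dict[str, ClinvarEvidence]]:
    """Generate a synthetic variant catalogue, score table and ClinVar map.

    Every emitted protein HGVS string round-trips through the package's own
    parser; truncating and unannotated variants carry no predictor scores.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.position_range
    positions = rng.choice(np.arange(lo, hi + 1), size=spec.n_variants, replace=False)
    cons_levels = list(spec.consequence_mix)
    cons_p = np.array([spec.consequence_mix[c] for c in cons_levels], dtype=float)

    records: list[VariantRecord] = []
    scores: dict[str, RawScores] = {}
    clinvar: dict[str, ClinvarEvidence] = {}
    for i, pos in enumerate(sorted(int(p) for p in positions)):
        consequence = Consequence(cons_levels[rng.choice(len(cons_levels), p=cons_p)])
        ref = AminoAcid(_RESIDUES[rng.integers(len(_RESIDUES))])
        base = 3 * pos - 2  # first coding position of the codon
        if consequence is Consequence.MISSENSE:
            alt = AminoAcid(
                _RESIDUES[rng.choice([j for j in range(20) if _RESIDUES[j] != ref.code3])]
            )
            b1, b2 = rng.choice(4, size=2, replace=False)
            cdna = f"c.{base}{_BASES[b1]}>{_BASES[b2]}"
            change = ProteinChange(ref, pos, alt, consequence)
        elif consequence is Consequence.FRAMESHIFT:
            cdna = f"c.{base}dup" if rng.random() < 0.5 else f"c.{base}_{base + 1}del"
            change = ProteinChange(ref, pos, None, consequence)
        else:
            b1, b2 = rng.choice(4, size=2, replace=False)
            cdna = f"c.{base}{_BASES[b1]}>{_BASES[b2]}"
            change = ProteinChange(ref, pos, AminoAcid("Ter"), consequence)

        rsid = f"rs9{600000 + i:08d}" if rng.random() < spec.p_has_rsid else None
        carriers_bc = int(rng.integers(0, 3))
        carriers_oc = int(rng.integers(0, 2))
        if carriers_bc + carriers_oc == 0:
            carriers_bc = 1

        labels = [
            list(spec.clinvar_label_probs)[
                rng.choice(
                    len(spec.clinvar_label_probs),
                    p=np.array(list(spec.clinvar_label_probs.values())),
                )
            ]
        ]
        if rng.random() < 0.25 and "Uncertain significance" not in labels:
            labels.append("Uncertain significance")
        has_plp = any(l in ("Pathogenic", "Likely pathogenic") for l in labels)
        clinical = "Pathogenic" if has_plp else "VUS"

        record = VariantRecord(
            hgvs_cdna=cdna,
            protein_change=change,
            rsid=rsid,
            carriers_bc=carriers_bc,
            carriers_oc=carriers_oc,
            clinical_classification=clinical,
            clinvar_aggregate=tuple(labels),
            clinvar_review="synthetic",
        )
        records.append(record)
        clinvar[record.key] = ClinvarEvidence.from_labels(labels)

        if consequence is Consequence.MISSENSE and rng.random() < spec.p_scores_available:
            sift_adverse = rng.random() < spec.score_adverse_weight
            poly_adverse = rng.random() < spec.score_adverse_weight
            sift = rng.uniform(0.0, 0.05) if sift_adverse else rng.uniform(0.06, 1.0)
            poly = rng.uniform(0.85, 1.0) if poly_adverse else rng.uniform(0.0, 0.84)
            scores[record.key] = RawScores(
                sift_score=round(float(sift), 3), polyphen_score=round(float(poly), 3)
            )
        else:
            scores[record.key] = RawScores()

    table = VariantTable(records)
    return table, scores, clinvar


# ---------------------------------------------------------------------------
# Writers (plain TSV, byte-stable ordering and formatting)


def write_cohort(patients: pd.DataFrame, path: str | Path) -> None:
    patients.to_csv(path, sep="\t", index=False)


def write_panel(
    table: VariantTable,
    scores: Mapping[str, RawScores],
    clinvar: Mapping[str, ClinvarEvidence],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write variants.tsv / predictions.tsv / clinvar.tsv into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": out / "variants.tsv",
        "predictions": out / "predictions.tsv",
        "clinvar": out / "clinvar.tsv",
    }
    with open(paths["variants"], "w", encoding="utf-8") as fh:
        fh.write(
            "hgvs_cdna\thgvs_protein\trsid\tcarriers_bc\tcarriers_oc\t"
            "clinical_classification\tclinvar_aggregate\tclinvar_review\n"
        )
        for r in table:
            fh.write(
                f"{r.hgvs_cdna}\t{r.protein_change.format()}\t{r.rsid or ''}\t"
                f"{r.carriers_bc}\t{r.carriers_oc}\t{r.clinical_classification}\t"
                f"{';'.join(r.clinvar_aggregate)}\t{r.clinvar_review}\n"
            )
    with open(paths["predictions"], "w", encoding="utf-8") as fh:
        fh.write("variant_key\tsift_score\tpolyphen_score\tsift_label\tpolyphen_label\n")
        for r in table:
            s = scores[r.key]
            sift = "" if s.sift_score is None else f"{s.sift_score:.3f}"
            poly = "" if s.polyphen_score is None else f"{s.polyphen_score:.3f}"
            fh.write(f"{r.key}\t{sift}\t{poly}\t{s.sift_label}\t{s.polyphen_label}\n")
    with open(paths["clinvar"], "w", encoding="utf-8") as fh:
        fh.write("variant_key\tlabels\n")
        for r in table:
            fh.write(f"{r.key}\t{';'.join(sorted(clinvar[r.key].labels))}\n")
    return paths
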