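"""End-to-end orchestration of the variant-interpretation stages.

``run_all`` reads the input tables, runs domain localization, predictor
classification, property analysis, priority triage, frequency comparison
and (when a patient table is supplied) cohort statistics, and writes one
TSV per stage plus a JSON summary.  Output ordering and float formatting
are fixed (p-values 4 dp, percentages 2 dp), so re-running on identical
inputs yields byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import datasets
from .cohort import compare_by_carrier
from .domains import DomainCategory, assign_all, load_domain_config
from .frequency import (
    carrier_frequency,
    compare_table,
    format_p,
    read_references,
)
from .predictions import (
    ThresholdConfig,
    UNKNOWN_PROFILE,
    classify,
    read_predictions,
)
from .properties import default_residue_properties, delta, report
from .rubric import prioritize_table
from .variants import Consequence, read_cohort_sizes, read_variant_table

logger = logging.getLogger("varprio")

__all__ = ["RunConfig", "PipelineError", "run_all"]


class PipelineError(RuntimeError):
    """A stage failure; ``stage`` names the stage for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    variants_path: Path
    predictions_path: Path
    out_dir: Path
    domains_path: Optional[Path] = None
    references_path: Optional[Path] = None
    patients_path: Optional[Path] = None
    cohort_sizes_path: Optional[Path] = None
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                logger.error("stage %s failed: %s", name, exc)
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the summary dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = _load_variants(config)
    domains, window = _load_domains(config)
    assignments = _run_domains(table, domains, window, out)
    profiles = _run_insilico(config, table, out)
    _run_properties(table, out)
    priority_report = _run_priority(table, assignments, profiles, out)
    n_freq = _run_frequency(config, table, out)
    if config.patients_path is not None:
        _run_cohort(config, out)

    counts_by_domain: dict[str, int] = {}
    for key, a in assignments.items():
        label = a.domain.name if a.category is DomainCategory.INSIDE else a.category.value
        counts_by_domain[label] = counts_by_domain.get(label, 0) + 1
    summary = {
        "n_variants": len(table),
        "n_carriers": sum(r.carriers_total for r in table),
        "carrier_pct_total": carrier_frequency(table, "all").percent,
        "carrier_pct_bc": carrier_frequency(table, "BC").percent,
        "carrier_pct_oc": carrier_frequency(table, "OC").percent,
        "counts_by_priority": {
            str(lvl): n for lvl, n in priority_report.counts_by_level.items()
        },
        "counts_by_domain": dict(sorted(counts_by_domain.items())),
        "n_frequency_comparisons": n_freq,
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %s", summary)
    return summary


@_stage("variants")
def _load_variants(config: RunConfig):
    sizes = (
        read_cohort_sizes(config.cohort_sizes_path)
        if config.cohort_sizes_path
        else datasets.load_study_cohort_sizes()
    )
    return read_variant_table(config.variants_path, sizes)


@_stage("domains")
def _load_domains(config: RunConfig):
    if config.domains_path is not None:
        return load_domain_config(config.domains_path)
    return datasets.load_default_domains()


@_stage("domains")
def _run_domains(table, domains, window, out: Path):
    assignments = assign_all(table, domains, window)
    with open(out / "domain_assignments.tsv", "w", encoding="utf-8") as fh:
        fh.write("variant_key\tposition\tcategory\tdomain\tdistance\n")
        for rec in table:
            a = assignments[rec.key]
            name = a.domain.name if a.domain is not None else ""
            dist = "inf" if a.distance_to_nearest == float("inf") else str(int(a.distance_to_nearest))
            fh.write(
                f"{rec.key}\t{rec.protein_change.position}\t{a.category.value}\t{name}\t{dist}\n"
            )
    return assignments


@_stage("insilico")
def _run_insilico(config: RunConfig, table, out: Path):
    raw = read_predictions(config.predictions_path)
    profiles = {}
    for rec in table:
        scores = raw.get(rec.key)
        profiles[rec.key] = classify(scores, config.thresholds) if scores else UNKNOWN_PROFILE
    with open(out / "prediction_calls.tsv", "w", encoding="utf-8") as fh:
        fh.write("variant_key\tsift_score\tpolyphen_score\tsift_call\tpolyphen_call\tconcordant\n")
        for rec in table:
            p = profiles[rec.key]
            sift = "" if p.sift_score is None else f"{p.sift_score:.3f}"
            poly = "" if p.polyphen_score is None else f"{p.polyphen_score:.3f}"
            fh.write(
                f"{rec.key}\t{sift}\t{poly}\t{p.sift_call.value}\t"
                f"{p.polyphen_call.value}\t{str(p.concordant).lower()}\n"
            )
    return profiles


@_stage("properties")
def _run_properties(table, out: Path):
    props = default_residue_properties()
    with open(out / "property_deltas.tsv", "w", encoding="utf-8") as fh:
        fh.write("variant_key\tref\talt\tsummary\n")
        for rec in table:
            pc = rec.protein_change
            if pc.consequence is not Consequence.MISSENSE:
                continue
            d = delta(pc.ref, pc.alt, props)
            fh.write(f"{rec.key}\t{pc.ref.code3}\t{pc.alt.code3}\t{report(d)}\n")


@_stage("priority")
def _run_priority(table, assignments, profiles, out: Path):
    rep = prioritize_table(table, assignments, profiles)
    with open(out / "priority.tsv", "w", encoding="utf-8") as fh:
        fh.write(
            "variant\tprotein_change\trsid\tdomain\ttype\tsift\tpolyphen\t"
            "property_summary\tclinvar\tpriority\tledger\n"
        )
        props = default_residue_properties()
        for row in rep.rows:
            rec, a, p = row.variant, row.assignment, row.profile
            pc = rec.protein_change
            domain = a.domain.name if a.domain is not None else "outside"
            sift = "" if p.sift_score is None else f"{p.sift_score:.3f}"
            poly = "" if p.polyphen_score is None else f"{p.polyphen_score:.3f}"
            prop = (
                report(delta(pc.ref, pc.alt, props))
                if pc.consequence is Consequence.MISSENSE
                else "truncating"
            )
            trace = ";".join(
                f"{e.rule}={'+' if e.applied else '-'}" for e in row.result.ledger
            )
            fh.write(
                f"{rec.hgvs_cdna}\t{pc.format()}\t{rec.rsid or ''}\t{domain}\t"
                f"{pc.consequence.value}\t{sift}\t{poly}\t{prop}\t"
                f"{';'.join(rec.clinvar_aggregate)}\t{row.result.level}\t{trace}\n"
            )
    return rep


@_stage("frequency")
def _run_frequency(config: RunConfig, table, out: Path) -> int:
    refs = (
        read_references(config.references_path)
        if config.references_path
        else datasets.load_study_references()
    )
    rows = compare_table(table, refs)
    with open(out / "freq_comparisons.tsv", "w", encoding="utf-8") as fh:
        fh.write("variant_key\tsource\tkind\tk1\tn1\tk2\tn2\todds_ratio\tp_two_sided\n")
        for row in rows:
            c = row.comparison.counts
            orr = row.comparison.odds_ratio
            or_str = "inf" if orr == float("inf") else f"{orr:.4g}"
            fh.write(
                f"{row.variant_key}\t{row.source_label}\t{row.kind}\t"
                f"{c.k1}\t{c.n1}\t{c.k2}\t{c.n2}\t{or_str}\t"
                f"{format_p(row.comparison.p_two_sided)}\n"
            )
    return len(rows)


# The stratified comparisons run for a supplied patient table: variable,
# tested level, and which diagnosis groups it applies to.
_COHORT_COMPARISONS = (
    ("age", None, ("BC", "OC")),
    ("bmi_class", "overweight", ("BC", "OC")),
    ("family_history", "first_degree", ("BC", "OC")),
    ("chemo_response", "complete", ("BC", "OC")),
    ("laterality", "bilateral", ("BC", "OC")),
    ("abortion", True, ("BC", "OC")),
)


@_stage("cohort")
def _run_cohort(config: RunConfig, out: Path):
    patients = pd.read_csv(config.patients_path, sep="\t")
    with open(out / "cohort_stats.tsv", "w", encoding="utf-8") as fh:
        fh.write(
            "group\tvariable\tlevel\tcarrier_stat\tnoncarrier_stat\t"
            "carrier_pct\tnoncarrier_pct\ttest\tp_two_sided\n"
        )
        for variable, level, groups in _COHORT_COMPARISONS:
            for group in groups:
                try:
                    cmp = compare_by_carrier(patients, variable, level=level, group=group)
                except (KeyError, ValueError):
                    continue  # variable absent or a stratum empty in this table
                cpct = "" if cmp.carrier_pct is None else str(cmp.carrier_pct)
                npct = "" if cmp.noncarrier_pct is None else str(cmp.noncarrier_pct)
                fh.write(
                    f"{group}\t{variable}\t{'' if level is None else level}\t"
                    f"{cmp.carrier_stat:.2f}\t{cmp.noncarrier_stat:.2f}\t"
                    f"{cpct}\t{npct}\t{cmp.test}\t{format_p(cmp.p_two_sided)}\n"
                )
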