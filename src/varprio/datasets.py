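"""Accessors for the packaged study data.

The package ships the published summary tables of a Jalisco (Mexico)
breast/ovarian cancer cohort screened for germline BRCA2 variants: the
13-variant catalogue with carrier counts and clinical labels, the VEP
SIFT/PolyPhen scores for its missense variants, reference-population
counts for frequency comparison, the BRCA2 domain intervals (UniProt
P51587 numbering), and the residue property scales.
"""

from __future__ import annotations

from contextlib import ExitStack
from importlib import resources
from pathlib import Path

from .domains import DomainAnnotation, load_domain_config
from .predictions import RawScores, read_predictions
from .frequency import ReferenceCount, read_references
from .properties import ResidueProperties, load_residue_properties
from .variants import CohortSizes, VariantTable, read_cohort_sizes, read_variant_table

__all__ = [
    "data_path",
    "load_study_variants",
    "load_study_predictions",
    "load_study_references",
    "load_study_cohort_sizes",
    "load_default_domains",
    "load_default_residue_properties",
]

_stack = ExitStack()
_cached: dict[str, Path] = {}


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file (materialized if zipped)."""
    if name not in _cached:
        ref = resources.files("varprio.data").joinpath(name)
        _cached[name] = _stack.enter_context(resources.as_file(ref))
    return _cached[name]


def load_study_cohort_sizes() -> CohortSizes:
    return read_cohort_sizes(data_path("cohort_sizes.json"))


def load_study_variants() -> VariantTable:
    """The 13-variant BRCA2 catalogue of the 140-patient Jalisco cohort."""
    return read_variant_table(
        data_path("jalisco_brca2_variants.tsv"), load_study_cohort_sizes()
    )


def load_study_predictions() -> dict[str, RawScores]:
    """SIFT/PolyPhen scores as annotated by VEP (absent for truncating and
    unannotated variants)."""
    return read_predictions(data_path("vep_predictions.tsv"))


def load_study_references() -> list[ReferenceCount]:
    """Carrier/allele counts for the same variants in other cohorts and in
    gnomAD/dbSNP."""
    return read_references(data_path("reference_frequencies.tsv"))


def load_default_domains() -> tuple[tuple[DomainAnnotation, ...], int]:
    """BRCA2 functional-domain intervals and the default boundary window."""
    return load_domain_config(data_path("brca2_domains.json"))


def load_default_residue_properties() -> ResidueProperties:
    return load_residue_properties(data_path("residue_properties.json"))
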