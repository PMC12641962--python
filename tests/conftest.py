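import pytest
from hypothesis import settings

import varprio as vp

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_table() -> vp.VariantTable:
    """The packaged 13-variant BRCA2 catalogue (140-patient cohort)."""
    return vp.datasets.load_study_variants()


@pytest.fixture(scope="session")
def default_domains():
    """(domains, boundary_window) from the packaged BRCA2 config."""
    return vp.datasets.load_default_domains()


@pytest.fixture(scope="session")
def study_scores():
    return vp.datasets.load_study_predictions()


@pytest.fixture(scope="session")
def study_profiles(study_table, study_scores):
    return {
        key: (vp.classify(study_scores[key]) if key in study_scores else vp.UNKNOWN_PROFILE)
        for key in study_table.keys
    }


@pytest.fixture(scope="session")
def study_assignments(study_table, default_domains):
    domains, window = default_domains
    return vp.assign_all(study_table, domains, window)


@pytest.fixture(scope="session")
def priority_report(study_table, study_assignments, study_profiles):
    return vp.prioritize_table(study_table, study_assignments, study_profiles)
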