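import pytest

from ari_triage.cohort_synth import CANDIDATE_PREDICTORS, CohortSpec, generate_cohort
from ari_triage.imputation import median_impute_by_outcome
from ari_triage.scores import ThresholdTable


@pytest.fixture(scope="session")
def thresholds():
    return ThresholdTable.default()


@pytest.fixture(scope="session")
def study_cohort():
    """A full-size synthetic cohort under the default study conditions."""
    return generate_cohort(CohortSpec(), seed=5)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for fast model fits (~1000 presentations)."""
    return generate_cohort(CohortSpec(n_children=250), seed=11)


@pytest.fixture(scope="session")
def completed_cohort(study_cohort):
    """The study cohort completed by outcome-grouped median imputation."""
    variables = [v for v in CANDIDATE_PREDICTORS if study_cohort[v].isna().any()]
    return median_impute_by_outcome(study_cohort, variables)
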