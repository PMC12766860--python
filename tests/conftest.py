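import pytest

from opmstage import (
    CohortCounts,
    ConfusionTable,
    ModelParams,
    derive_unit_costs,
)
from opmstage import study


@pytest.fixture(scope="session")
def study_table() -> ConfusionTable:
    """The observed 2x2 table: 12 TP, 5 FP, 4 FN, 88 TN (n = 109)."""
    return ConfusionTable(tp=12, fp=5, fn=4, tn=88)


@pytest.fixture(scope="session")
def study_counts(study_table) -> CohortCounts:
    return CohortCounts.from_table(study_table)


@pytest.fixture(scope="session")
def derived_costs(study_counts):
    """Unit costs back-solved from the published per-patient aggregates."""
    return derive_unit_costs(study.S1_TOTAL, study.S3_DELTA, study.S2_DELTA, study_counts)


@pytest.fixture(scope="session")
def base_params(study_counts, derived_costs) -> ModelParams:
    return ModelParams.from_observed(study_counts, derived_costs)
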