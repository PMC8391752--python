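import warnings

import numpy as np
import pytest

from fldpred.cohort import FeatureDef, FeatureSchema, SubjectHistory, Visit
from fldpred.preprocessing import FeatureTable, impute, zscore_fit_apply
from fldpred.simulate import GeneratorParams, generate_cohort


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-subject default-condition cohort shared across tests."""
    return generate_cohort(GeneratorParams(n_subjects=300, seed=7))


@pytest.fixture(scope="session")
def small_table(small_cohort):
    table = FeatureTable.from_cohort(small_cohort)
    from fldpred.preprocessing import drop_high_missing

    table, _ = drop_high_missing(table, 0.9)
    return zscore_fit_apply(impute(table))


@pytest.fixture
def tiny_schema():
    return FeatureSchema(
        (
            FeatureDef("x1", "numeric"),
            FeatureDef("x2", "numeric"),
            FeatureDef("q1", "categorical", (0, 3)),
        )
    )


def make_history(months, labels, values=None, subject_id="S1", gender="male", birth_year=1960):
    """Build a SubjectHistory with features x1 (numeric) and q1 (categorical)."""
    visits = []
    for i, (m, lab) in enumerate(zip(months, labels)):
        val = values[i] if values is not None else float(i)
        visits.append(
            Visit(
                subject_id=subject_id,
                year=2010 + m // 12,
                month=m % 12 + 1,
                numeric={"x1": float(val)},
                categorical={"q1": int(round(val)) % 4},
                fld_label=int(lab),
            )
        )
    return SubjectHistory(subject_id=subject_id, gender=gender, birth_year=birth_year, visits=visits)


@pytest.fixture
def history_factory():
    return make_history
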