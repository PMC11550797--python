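import numpy as np
import pytest

from adrsignal.cohort import CYP_FLAGS, CaseRecord, DrugCatalog, RawCohort
from adrsignal.curation import CurationConfig
from adrsignal.synthetic import CohortSpec, build_drug_catalog, sample_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_spec():
    return CohortSpec(n_cases=300, n_repeat_visits=25, n_missing_medication=2,
                      catalog_size=80, seed=7)


@pytest.fixture
def small_catalog(small_spec):
    return build_drug_catalog(small_spec, small_spec.rng())


@pytest.fixture
def small_cohort(small_spec, small_catalog):
    r = small_spec.rng()
    build_drug_catalog(small_spec, r)  # advance rng identically to pipeline order
    return sample_cohort(small_spec, small_catalog, r)


def make_record(case_id, patient_id=None, visit_index=1, drugs=("aspirin",),
                age=70.0, sex="female", outcome=0):
    return CaseRecord(case_id=case_id,
                      patient_id=patient_id if patient_id is not None else case_id,
                      visit_index=visit_index, age=age, sex=sex,
                      drugs=tuple(drugs), outcome=outcome)


@pytest.fixture
def plain_config():
    return CurationConfig(min_count=1, top_n=100)


def catalog_from_names(names, **flag_sets):
    """Small hand-built catalog; flag_sets maps flag name -> set of drugs."""
    import pandas as pd

    table = pd.DataFrame({"drug_name": list(names)})
    for col in ("is_combination", "is_unspecific", "is_supplement", *CYP_FLAGS):
        marked = flag_sets.get(col, set())
        table[col] = [n in marked for n in names]
    return DrugCatalog(table=table)


def cohort_of(*records):
    return RawCohort(records=list(records))
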