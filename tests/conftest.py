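import numpy as np
import pandas as pd
import pytest

from clical.cohort import COHORT_COLUMNS, CohortTable
from clical.simulate import GeneratorConfig, generate


def make_cohort(rows: list[dict]) -> CohortTable:
    """Build a cohort from partial row dicts; unspecified fields get
    scoreable defaults."""
    base = {
        "patient_id": None,
        "sex": "female",
        "age_years": 70.0,
        "age_group": "older",
        "braf": "wildtype",
        "cns_met": "no",
        "ldh_ratio": np.nan,
        "ldh_category": "normal",
        "eosinophil_category": "normal",
        "neutrophils": np.nan,
        "lymphocytes": np.nan,
        "nlr_value": np.nan,
        "nlr_category": "normal",
        "prior_treatment": "naive",
        "pre_target": "no",
        "ici_agent": "nivolumab",
        "os_months": 12.0,
        "os_event": 1,
        "response": "unknown",
    }
    records = []
    for i, row in enumerate(rows):
        rec = dict(base)
        rec["patient_id"] = f"P{i:03d}"
        rec.update(row)
        records.append(rec)
    df = pd.DataFrame(records, columns=list(COHORT_COLUMNS))
    return CohortTable(df)


@pytest.fixture
def toy_surv():
    """3-subject hand-checkable survival fixture."""
    return np.array([5.0, 8.0, 12.0]), np.array([1, 1, 0])


@pytest.fixture(scope="session")
def cohort_2000():
    """Mid-size seeded synthetic cohort shared across tests."""
    cohort, manifest = generate(GeneratorConfig(n=2000, seed=42))
    return cohort, manifest


@pytest.fixture(scope="session")
def cohort_50k():
    """Large cohort for stochastic marginal/hazard recovery checks."""
    cohort, manifest = generate(GeneratorConfig(n=50_000, seed=11))
    return cohort, manifest


@pytest.fixture(scope="session")
def cohort_578():
    """Default-size seeded synthetic cohort."""
    cohort, manifest = generate(GeneratorConfig(n=578, seed=7))
    return cohort, manifest
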