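import numpy as np
import pandas as pd
import pytest

from ttescreen.cohort import classify_pd_cases
from ttescreen.experiments import confounded_null_config
from ttescreen.simulate import default_config, generate_registry, make_toy_fixture


@pytest.fixture(scope="session")
def small_registry():
    """A small default-condition registry shared across read-only tests."""
    snapshot, truth = generate_registry(default_config(n_persons=3000, seed=42))
    return snapshot, truth


@pytest.fixture(scope="session")
def null_trial_registry():
    """Confounded-null registry: one target drug, two comparators."""
    snapshot, truth = generate_registry(confounded_null_config(2500, seed=7))
    cases = classify_pd_cases(snapshot)
    return snapshot, truth, cases


@pytest.fixture()
def classify_fixture():
    return make_toy_fixture("classify_basic")


def build_snapshot(persons_rows, rx_rows, dx_rows=(), coverage=("2004-01-01", "2015-12-31"),
                   catalogue=None):
    """Hand-built snapshot helper for micro-tests."""
    from ttescreen.registry import RegistrySnapshot

    persons = pd.DataFrame(
        persons_rows,
        columns=["person_id", "sex", "birth_year", "education_level",
                 "emigration_date", "death_year", "death_month"],
    )
    persons["emigration_date"] = pd.to_datetime(persons["emigration_date"])
    persons["death_year"] = persons["death_year"].astype("Int64")
    persons["death_month"] = persons["death_month"].astype("Int64")
    rx = pd.DataFrame(
        rx_rows, columns=["person_id", "atc_code", "dispense_date", "reimbursement_icd"]
    )
    rx["dispense_date"] = pd.to_datetime(rx["dispense_date"])
    dx = pd.DataFrame(list(dx_rows), columns=["person_id", "icd10_code", "visit_date"])
    dx["visit_date"] = pd.to_datetime(dx["visit_date"])
    codes = catalogue or sorted(set(rx["atc_code"])) or ["N04BA02", "N04BD01"]
    cat = pd.DataFrame({"atc_code": codes, "drug_name": codes})
    return RegistrySnapshot(
        prescriptions=rx, persons=persons, diagnoses=dx, catalogue=cat,
        coverage=(pd.Timestamp(coverage[0]), pd.Timestamp(coverage[1])),
    )


def person(pid, birth_year=1940, sex="M", education="secondary",
           emigration=None, death_year=None, death_month=None):
    return (pid, sex, birth_year, education, emigration, death_year, death_month)
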