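"""Prescription-based Parkinson-disease case classification and validation.

A person is classified as a PD case by either of two prescription rules:

1. at least four fills of MAO-B inhibitors (ATC group N04BD), or
2. at least four fills of levodopa (default ATC group N04BA) together with
   at least one of those fills carrying the PD reimbursement code G20.

The diagnosis date is the dispense date of the last (fourth) prescription
needed to satisfy the rule.  Incident cases only: any person with an
antiparkinsonian fill (ATC prefix N04) during the prevalence-exclusion year
(by default the first coverage year) is removed.

Classification is validated against a diagnosis-code reference standard
(default: at least two specialist-care G20 records), yielding positive
predictive value and sensitivity.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .registry import RegistrySnapshot

__all__ = ["ClassificationRules", "classify_pd_cases", "validate_classification"]


@dataclasses.dataclass
class ClassificationRules:
    maob_prefix: str = "N04BD"
    levodopa_prefixes: tuple[str, ...] = ("N04BA",)
    reimbursement_code: str = "G20"
    min_fills: int = 4
    antiparkinson_prefix: str = "N04"
    exclusion_year: int | None = None  # default: first coverage year
    distinct_dates: bool = False  # require the qualifying fills on distinct dates
    collapse_same_day: bool = False  # collapse same-day duplicate fills


def _nth_fill_date(fills: pd.DataFrame, n: int, distinct: bool, collapse: bool) -> pd.Series:
    """Per person, the dispense date of the n-th qualifying fill (NaT if <n)."""
    f = fills.sort_values(["person_id", "dispense_date"], kind="stable")
    if distinct or collapse:
        f = f.drop_duplicates(["person_id", "dispense_date"])
    f = f.assign(_k=f.groupby("person_id").cumcount())
    nth = f[f["_k"] == n - 1].set_index("person_id")["dispense_date"]
    nth.name = "diagnosis_date"
    return nth


def classify_pd_cases(
    snapshot: RegistrySnapshot, rules: ClassificationRules | None = None
) -> pd.DataFrame:
    """Apply the prescription rules; one row per case.

    Returns a DataFrame with columns person_id, diagnosis_date,
    qualifying_rule ('maob' or 'levodopa_reimb') and age_at_diagnosis.
    When both rules are met, the rule reaching its fourth qualifying fill
    first wins (tie broken toward the MAO-B rule).
    """
    rules = rules or ClassificationRules()
    excl_year = rules.exclusion_year
    if excl_year is None:
        excl_year = snapshot.coverage[0].year
    rx = snapshot.prescriptions
    atc = rx["atc_code"].astype(str)

    prevalent = set(
        rx.loc[
            atc.str.startswith(rules.antiparkinson_prefix)
            & (rx["dispense_date"].dt.year == excl_year),
            "person_id",
        ]
    )

    maob = rx[atc.str.startswith(rules.maob_prefix)]
    maob_date = _nth_fill_date(
        maob, rules.min_fills, rules.distinct_dates, rules.collapse_same_day
    )

    levo = rx[atc.str.startswith(tuple(rules.levodopa_prefixes))]
    levo_date = _nth_fill_date(
        levo, rules.min_fills, rules.distinct_dates, rules.collapse_same_day
    )
    has_reimb = set(
        levo.loc[levo["reimbursement_icd"] == rules.reimbursement_code, "person_id"]
    )
    levo_date = levo_date[levo_date.index.isin(has_reimb)]

    both = pd.DataFrame({"maob": maob_date, "levodopa_reimb": levo_date})
    both = both[~both.index.isin(prevalent)]
    if both.empty:
        return pd.DataFrame(
            columns=["person_id", "diagnosis_date", "qualifying_rule", "age_at_diagnosis"]
        )
    # earliest qualifying rule wins; ties resolved toward the MAO-B rule
    rule = np.where(
        both["maob"].notna() & (both["maob"].fillna(pd.Timestamp.max) <= both[
            "levodopa_reimb"
        ].fillna(pd.Timestamp.max)),
        "maob",
        "levodopa_reimb",
    )
    date = both.min(axis=1)
    keep = date.notna()
    cases = pd.DataFrame(
        {
            "person_id": both.index[keep],
            "diagnosis_date": date[keep].to_numpy(),
            "qualifying_rule": rule[keep],
        }
    ).sort_values("person_id").reset_index(drop=True)

    by = snapshot.persons.set_index("person_id")["birth_year"]
    birth = pd.to_datetime(
        {"year": by.loc[cases["person_id"]].astype(int).to_numpy(), "month": 1, "day": 1}
    )
    cases["age_at_diagnosis"] = (
        cases["diagnosis_date"].to_numpy() - birth.to_numpy()
    ) / np.timedelta64(1, "s") / (365.25 * 86400)
    return cases


def validate_classification(
    cases: pd.DataFrame,
    diagnoses: pd.DataFrame,
    reference_code: str = "G20",
    min_reference_codes: int = 2,
) -> dict:
    """PPV and sensitivity of the classification against a code-count reference.

    The reference standard is "at least ``min_reference_codes`` diagnosis
    records with ``reference_code``".  PPV is None (undefined) when no
    person was classified.
    """
    classified = set(cases["person_id"])
    counts = (
        diagnoses.loc[diagnoses["icd10_code"] == reference_code]
        .groupby("person_id")
        .size()
    )
    reference = set(counts.index[counts >= min_reference_codes])
    tp = len(classified & reference)
    result = {
        "tp": tp,
        "fp": len(classified) - tp,
        "fn": len(reference) - tp,
        "n_classified": len(classified),
        "n_reference": len(reference),
        "ppv": tp / len(classified) if classified else None,
        "sensitivity": tp / len(reference) if reference else None,
    }
    return result
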