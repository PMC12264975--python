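"""Baseline covariate assembly: demographics, RxRisk index, comorbidity flags.

Comorbidity is measured from the prescription channel alone, in the style of
the RxRisk index: drug fills are mapped to chronic-condition categories via
ATC prefixes, and a person's index is the sum of the mortality-association
weights of the distinct categories filled during a two-year baseline
lookback.  The same lookback defines the binary flags for the most common
comorbidity categories, which enter the propensity model individually.

The category/prefix/weight mapping is configurable.  The default shipped
here is a synthetic 46-category mapping (plausible chronic-condition labels,
one level-2 ATC prefix per category, weights in [-1, 7]); it mirrors the
structure of published prescription-based comorbidity indices without
reproducing any proprietary weight table, and is sufficient for synthetic
registries whose marker drugs are drawn from the same prefixes.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .atc import parse_atc_levels

__all__ = [
    "load_rxrisk_mapping",
    "default_rxrisk_mapping",
    "assign_categories",
    "compute_rxrisk",
    "top_comorbidities",
    "assemble_covariates",
]

MAPPING_COLUMNS = ["category_id", "label", "atc_prefix", "weight"]

# Synthetic default mapping: 46 chronic-condition categories keyed by ATC
# level-2 prefixes (first match wins, in row order).  Weights are synthetic,
# chosen in [-1, 7] with heavier weights on conditions strongly associated
# with one-year mortality.
_DEFAULT_MAPPING_CSV = """\
category_id,label,atc_prefix,weight
1,parkinsonism,N04,1.5
2,acid_related_disorders,A03,0.5
3,antiemesis,A04,3.0
4,liver_disease,A05,2.5
5,constipation,A06,1.0
6,inflammatory_bowel_disease,A07,1.0
7,obesity,A08,0.5
8,diabetes,A10,2.0
9,vitamin_deficiency,A11,0.5
10,mineral_supplement,A12,1.0
11,anticoagulation,B01,2.0
12,bleeding_disorder,B02,2.5
13,anaemia,B03,2.0
14,fluid_electrolyte,B05,3.5
15,heart_failure,C01,4.0
16,hypertension_other,C02,1.0
17,diuretic_use,C03,2.5
18,varicose_haemorrhoid,C05,-0.5
19,ischaemic_heart_disease,C07,1.5
20,calcium_channel_hypertension,C08,0.5
21,fungal_skin_infection,D01,0.0
22,psoriasis,D05,0.5
23,skin_infection,D06,0.5
24,dermatitis_steroid,D07,0.5
25,gynaecological_infection,G01,0.0
26,contraception_gynaecology,G02,-1.0
27,hormone_replacement,G03,-0.5
28,pituitary_disorder,H01,3.0
29,systemic_steroid_disease,H02,3.5
30,calcium_homeostasis,H05,4.0
31,systemic_fungal_infection,J02,3.0
32,tuberculosis,J04,2.0
33,hiv_antiviral,J05,1.5
34,malignancy,L01,7.0
35,endocrine_cancer_therapy,L02,4.5
36,immunostimulant,L03,5.0
37,transplant_immunosuppression,L04,4.0
38,muscle_relaxant,M03,1.0
39,gout,M04,1.0
40,osteoporosis,M05,1.5
41,epilepsy,N03,2.0
42,psychotic_illness,N05,2.5
43,dementia,N07,5.5
44,protozoal_infection,P01,0.5
45,chronic_airways_disease,R03,2.0
46,allergy,R06,-0.5
"""


def default_rxrisk_mapping() -> pd.DataFrame:
    """The built-in synthetic 46-category mapping (one prefix per category)."""
    return load_rxrisk_mapping(io.StringIO(_DEFAULT_MAPPING_CSV))


def load_rxrisk_mapping(source) -> pd.DataFrame:
    """Load and validate a category mapping CSV.

    Columns: ``category_id`` (int), ``label``, ``atc_prefix``, ``weight``
    (real).  A category may span several rows (one per prefix); matching is
    first-match-wins in row order.
    """
    df = pd.read_csv(source)
    missing = [c for c in MAPPING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"RxRisk mapping lacks columns {missing}")
    df = df[MAPPING_COLUMNS].copy()
    df["category_id"] = df["category_id"].astype(int)
    df["weight"] = df["weight"].astype(float)
    for prefix in df["atc_prefix"]:
        parse_atc_levels(prefix)
    # one weight per category
    w = df.groupby("category_id")["weight"].nunique()
    if (w > 1).any():
        bad = w.index[w > 1][0]
        raise ValueError(f"category {bad} has conflicting weights across prefixes")
    return df


def category_weights(mapping: pd.DataFrame) -> pd.Series:
    return mapping.drop_duplicates("category_id").set_index("category_id")["weight"]


def assign_categories(atc_codes: pd.Series, mapping: pd.DataFrame) -> pd.Series:
    """Map ATC codes to category ids (NaN when no prefix matches).

    Rows of the mapping are tried in order; the first matching prefix wins.
    A code matches a row when it starts with the row's prefix; matching is
    vectorized by truncating all codes to each prefix length present in the
    mapping and resolving collisions by mapping-row order.
    """
    codes = atc_codes.to_numpy(dtype="U7")
    best_row = np.full(len(codes), len(mapping), dtype=np.int64)
    category = np.full(len(codes), -1, dtype=np.int64)
    prefixes = mapping["atc_prefix"].to_numpy()
    cat_ids = mapping["category_id"].to_numpy()
    for length in sorted({len(p) for p in prefixes}):
        lookup: dict[str, int] = {}
        for row_i, p in enumerate(prefixes):
            if len(p) == length and p not in lookup:
                lookup[p] = row_i
        if not lookup:
            continue
        trunc = codes.astype(f"U{length}")
        rows = np.array([lookup.get(t, -1) for t in trunc], dtype=np.int64)
        hit = (rows >= 0) & (rows < best_row)
        best_row[hit] = rows[hit]
        category[hit] = cat_ids[rows[hit]]
    out = pd.Series(category.astype(float), index=atc_codes.index)
    out[category < 0] = np.nan
    return out


def _categorized_fills(prescriptions: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Fills annotated with their comorbidity category, cached per snapshot.

    Categorizing a registry's full prescription table is the costly step of
    covariate assembly and is identical across the trials of a screen, so
    the result is memoized per prescriptions table, keyed by the mapping.
    """
    from ._cache import memoize_by_id

    def _compute():
        fills = prescriptions[["person_id", "atc_code", "dispense_date"]].copy()
        fills["category_id"] = assign_categories(fills["atc_code"], mapping)
        return fills.dropna(subset=["category_id"])

    key = ("rxrisk", tuple(mapping["atc_prefix"]), tuple(mapping["category_id"]))
    return memoize_by_id(prescriptions, key, _compute)


def _lookback_categories(
    initiations: pd.DataFrame,
    prescriptions: pd.DataFrame,
    mapping: pd.DataFrame,
    lookback_years: float = 2.0,
) -> pd.DataFrame:
    """Long table (init_idx, category_id) of categories present in the
    half-open window [baseline - lookback, baseline) of each initiation.

    ``initiations`` must carry columns person_id and baseline_date; its index
    is preserved as ``init_idx``.
    """
    fills = _categorized_fills(prescriptions, mapping)
    init = initiations[["person_id", "baseline_date"]].rename_axis("init_idx").reset_index()
    merged = init.merge(fills, on="person_id", how="inner")
    # window open at both ends: a fill exactly `lookback` before baseline,
    # or on the baseline date itself, is outside the lookback
    lb = merged["baseline_date"] - pd.DateOffset(months=int(round(lookback_years * 12)))
    in_window = (merged["dispense_date"] > lb) & (
        merged["dispense_date"] < merged["baseline_date"]
    )
    hits = merged.loc[in_window, ["init_idx", "category_id"]].drop_duplicates()
    hits["category_id"] = hits["category_id"].astype(int)
    return hits


def compute_rxrisk(
    prescriptions: pd.DataFrame,
    person_id,
    baseline_date,
    mapping: pd.DataFrame,
    lookback_years: float = 2.0,
) -> float:
    """RxRisk comorbidity index for one person at one baseline date.

    Sum of weights over the distinct categories matched by at least one fill
    in the half-open window [baseline - lookback, baseline); each category
    counts once however many fills match it.
    """
    init = pd.DataFrame(
        {"person_id": [person_id], "baseline_date": [pd.Timestamp(baseline_date)]}
    )
    hits = _lookback_categories(init, prescriptions, mapping, lookback_years)
    w = category_weights(mapping)
    return float(w.loc[hits["category_id"]].sum())


def top_comorbidities(
    initiations: pd.DataFrame,
    prescriptions: pd.DataFrame,
    mapping: pd.DataFrame,
    k: int = 20,
    lookback_years: float = 2.0,
) -> list[int]:
    """The ``k`` most prevalent comorbidity categories across initiations.

    Prevalence is the share of initiations with the category present in the
    baseline lookback; ties are broken toward the lower ``category_id``.
    Categories with zero prevalence are never returned.
    """
    hits = _lookback_categories(initiations, prescriptions, mapping, lookback_years)
    counts = hits.groupby("category_id").size()
    if counts.empty:
        return []
    ranked = counts.reset_index(name="n").sort_values(
        ["n", "category_id"], ascending=[False, True]
    )
    return ranked["category_id"].head(k).astype(int).tolist()


def _age_years(dates: pd.Series, birth_year: pd.Series) -> pd.Series:
    """Fractional age in years measured from January 1 of the birth year."""
    birth = pd.to_datetime({"year": birth_year.astype(int), "month": 1, "day": 1})
    return (dates.to_numpy() - birth.to_numpy()) / np.timedelta64(1, "s") / (365.25 * 86400)


def assemble_covariates(
    trial,
    snapshot,
    mapping: pd.DataFrame | None = None,
    categories: list[int] | None = None,
    k: int = 20,
    lookback_years: float = 2.0,
) -> pd.DataFrame:
    """Build the baseline covariate table for a trial cohort.

    One row per initiation with columns: person_id, arm (1 = target),
    sex, education, age_at_diagnosis (PD-mode only), age_at_initiation,
    initiation_year, rxrisk_index, and binary flags ``c<id>`` for the chosen
    comorbidity categories (the ``k`` most common in this cohort when
    ``categories`` is not given explicitly).  Education missingness is its
    own level, so the table has no missing cells.
    """
    if mapping is None:
        mapping = default_rxrisk_mapping()
    init = trial.initiations.reset_index(drop=True)
    if init.empty:
        raise ValueError("cannot assemble covariates for an empty cohort")
    persons = snapshot.persons.set_index("person_id")
    missing = [p for p in init["person_id"] if p not in persons.index]
    if missing:
        raise ValueError(f"initiation person_id {missing[0]!r} not in persons table")
    sub = persons.loc[init["person_id"]].reset_index()

    out = pd.DataFrame(
        {
            "person_id": init["person_id"],
            "arm": (init["arm"] == "target").astype(int),
            "sex": sub["sex"],
            "education": sub["education_level"].fillna("missing"),
            "age_at_initiation": _age_years(init["baseline_date"], sub["birth_year"]),
            "initiation_year": init["baseline_date"].dt.year.astype(float),
        }
    )
    if "diagnosis_date" in init.columns and init["diagnosis_date"].notna().all():
        out.insert(
            4, "age_at_diagnosis", _age_years(init["diagnosis_date"], sub["birth_year"])
        )

    hits = _lookback_categories(init, snapshot.prescriptions, mapping, lookback_years)
    w = category_weights(mapping)
    rx = hits.merge(w.rename("weight"), left_on="category_id", right_index=True)
    out["rxrisk_index"] = (
        rx.groupby("init_idx")["weight"].sum().reindex(out.index).fillna(0.0)
    )
    if categories is None:
        counts = hits.groupby("category_id").size()
        ranked = counts.reset_index(name="n").sort_values(
            ["n", "category_id"], ascending=[False, True]
        )
        categories = ranked["category_id"].head(k).astype(int).tolist()
    present = hits.assign(flag=1).pivot_table(
        index="init_idx", columns="category_id", values="flag", fill_value=0
    )
    for cid in categories:
        col = present[cid] if cid in present.columns else 0
        out[f"c{cid}"] = pd.Series(col, index=out.index).fillna(0).astype(int)
    out.attrs["categories"] = list(categories)
    assert not out.isna().any().any()
    return out
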