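"""Cohort profiling: demographics, treatment, mortality, coverage and costs.

Given any set of beneficiary ids, :func:`profile_cohort` computes the
descriptors used in the per-source and selected-population tables: age
(study_year − birth_year; mean, population SD, nearest-rank IQR), % male,
treatment rates (≥3 reimbursements on distinct dates in the study year, per
psychotropic class), in-year mortality, CMUC coverage restricted to the
under-60 population (benefit eligibility changes at 60), comorbidity-flag
rates, and summed reimbursed amounts per cost category.

Comorbidity flags and annual costs are tabulated as carried on the
beneficiary rows; deriving them from claims is out of scope here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .code_sets import CodeSet
from .data_model import COMORBIDITY_NAMES, COST_NAMES, ClaimsBundle
from .selection import SelectionConfig, _match

__all__ = [
    "CohortProfile",
    "profile_cohort",
    "mortality_rate_pct",
    "cmuc_rate_under60_pct",
    "drug_class_users",
]

#: profiled psychotropic classes -> registry code-set name
PSYCHOTROPIC_CLASSES = {
    "antidepressant": "ANTIDEPRESSANT",
    "anxiolytic": "ANXIOLYTIC",
    "neuroleptic": "NEUROLEPTIC",
    "hypnotic": "HYPNOTIC",
}


@dataclass(frozen=True)
class CohortProfile:
    n: int
    age_mean: float | None
    age_sd: float | None
    age_iqr_low: float | None
    age_iqr_high: float | None
    pct_male: float | None
    pct_antidepressant: float | None
    pct_anxiolytic: float | None
    pct_neuroleptic: float | None
    pct_hypnotic: float | None
    pct_any_psychotropic: float | None
    mortality_pct: float | None
    cmuc_pct_under60: float | None
    comorbidity_pcts: dict[str, float]
    cost_totals: dict[str, float]

    def to_series(self) -> pd.Series:
        """Flat key-value view mirroring the report layout."""
        d: dict[str, float | int | None] = {
            "n": self.n,
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "age_iqr_low": self.age_iqr_low,
            "age_iqr_high": self.age_iqr_high,
            "pct_male": self.pct_male,
            "mortality_pct": self.mortality_pct,
            "cmuc_pct_under60": self.cmuc_pct_under60,
        }
        for name in COMORBIDITY_NAMES:
            d[f"pct_comorb_{name}"] = self.comorbidity_pcts.get(name)
        for cls in PSYCHOTROPIC_CLASSES:
            d[f"pct_{cls}"] = getattr(self, f"pct_{cls}")
        d["pct_any_psychotropic"] = self.pct_any_psychotropic
        for name, total in self.cost_totals.items():
            d[f"cost_{name}"] = total
        return pd.Series(d)


def _nearest_rank(sorted_values: np.ndarray, p: float) -> float:
    """Nearest-rank quantile: the ceil(p*n)-th smallest value (1-based)."""
    n = len(sorted_values)
    k = max(1, math.ceil(p * n))
    return float(sorted_values[k - 1])


def drug_class_users(
    bundle: ClaimsBundle, code_set: CodeSet, config: SelectionConfig | None = None
) -> frozenset:
    """Ids with ≥3 dispensings of the class on distinct dates in the study year."""
    config = config or SelectionConfig()
    disp = bundle.dispensings
    if len(disp) == 0:
        return frozenset()
    mask = _match(disp["atc"], code_set) & (disp["date"].dt.year == bundle.study_year)
    hits = disp[mask.to_numpy()]
    if config.distinct_dates:
        counts = hits.groupby("beneficiary_id")["date"].nunique()
    else:
        counts = hits.groupby("beneficiary_id")["date"].size()
    return frozenset(counts.index[counts >= config.ad_min_dispensings])


def mortality_rate_pct(bundle: ClaimsBundle, ids: frozenset) -> float:
    """Percentage of the cohort whose administrative death date falls in the
    study year (deaths in other years do not count)."""
    ids = frozenset(ids)
    if not ids:
        raise ValueError("mortality rate undefined for an empty cohort")
    ben = bundle.beneficiaries
    sub = ben[ben["id"].isin(ids)]
    died = sub["death_date"].notna() & (sub["death_date"].dt.year == bundle.study_year)
    return 100.0 * int(died.sum()) / len(ids)


def cmuc_rate_under60_pct(bundle: ClaimsBundle, ids: frozenset) -> float | None:
    """CMUC coverage rate among cohort members aged under 60; ``None`` when
    the cohort has no under-60 members (rate undefined)."""
    ids = frozenset(ids)
    if not ids:
        raise ValueError("CMUC rate undefined for an empty cohort")
    ben = bundle.beneficiaries
    sub = ben[ben["id"].isin(ids)]
    young = sub[(bundle.study_year - sub["birth_year"]) < 60]
    if len(young) == 0:
        return None
    return 100.0 * int(young["cmuc"].sum()) / len(young)


def profile_cohort(
    bundle: ClaimsBundle, ids, config: SelectionConfig | None = None
) -> CohortProfile:
    """Full cohort profile for an id set; ``n=0`` profile with absent
    statistics (and zero cost totals) for an empty set."""
    config = config or SelectionConfig()
    ids = frozenset(ids)
    unknown = ids - bundle.beneficiary_ids
    if unknown:
        raise ValueError(f"{len(unknown)} id(s) not in bundle, e.g. {sorted(unknown)[:3]}")

    if not ids:
        return CohortProfile(
            n=0,
            age_mean=None, age_sd=None, age_iqr_low=None, age_iqr_high=None,
            pct_male=None,
            pct_antidepressant=None, pct_anxiolytic=None,
            pct_neuroleptic=None, pct_hypnotic=None, pct_any_psychotropic=None,
            mortality_pct=None, cmuc_pct_under60=None,
            comorbidity_pcts={name: float("nan") for name in COMORBIDITY_NAMES},
            cost_totals={**{name: 0.0 for name in COST_NAMES}, "total": 0.0},
        )

    ben = bundle.beneficiaries
    sub = ben[ben["id"].isin(ids)]
    n = len(sub)
    ages = (bundle.study_year - sub["birth_year"]).to_numpy(dtype=float)
    ages_sorted = np.sort(ages)

    class_users = {
        cls: drug_class_users(bundle, config.registry[reg], config)
        for cls, reg in PSYCHOTROPIC_CLASSES.items()
    }
    any_psy = frozenset().union(*class_users.values())

    comorbidity_pcts = {
        name: 100.0 * int(sub[f"comorb_{name}"].sum()) / n for name in COMORBIDITY_NAMES
    }
    cost_totals = {name: float(sub[f"cost_{name}"].sum()) for name in COST_NAMES}
    cost_totals["total"] = float(sum(cost_totals.values()))

    return CohortProfile(
        n=n,
        age_mean=float(ages.mean()),
        age_sd=float(ages.std(ddof=0)),
        age_iqr_low=_nearest_rank(ages_sorted, 0.25),
        age_iqr_high=_nearest_rank(ages_sorted, 0.75),
        pct_male=100.0 * int((sub["sex"] == "male").sum()) / n,
        pct_antidepressant=100.0 * len(ids & class_users["antidepressant"]) / n,
        pct_anxiolytic=100.0 * len(ids & class_users["anxiolytic"]) / n,
        pct_neuroleptic=100.0 * len(ids & class_users["neuroleptic"]) / n,
        pct_hypnotic=100.0 * len(ids & class_users["hypnotic"]) / n,
        pct_any_psychotropic=100.0 * len(ids & any_psy) / n,
        mortality_pct=mortality_rate_pct(bundle, ids),
        cmuc_pct_under60=cmuc_rate_under60_pct(bundle, ids),
        comorbidity_pcts=comorbidity_pcts,
        cost_totals=cost_totals,
    )
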