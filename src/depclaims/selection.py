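"""Case-selection methods A–E and the bipolar exclusion.

Five methods of decreasing reliability identify persons using significant
healthcare resources for depression in a claims bundle, all based on ICD-10
codes F32–F39 and a ≥3-reimbursement antidepressant criterion:

* **A** — active long-term-condition (ALD) full coverage for depression
  during the study year.
* **B** — depression as principal *or associated* diagnosis of a psychiatric
  hospital stay, or as *principal* diagnosis of a general hospital stay,
  within the study year (1-year window) or the last two calendar years.
* **C** — current antidepressant treatment (≥3 reimbursements in the study
  year) *and* a B-qualifying stay within the last 5 calendar years.
* **D** — depression as *associated* diagnosis of a general hospital stay
  (1- or 2-year window) — the least reliable diagnostic position.
* **E** — current antidepressant treatment *and* a D-qualifying stay within
  the last 5 calendar years.

Persons with a hospital diagnosis of bipolar disorder (F30/F31) in the last
5 calendar years, or at least one dispensing of a specific bipolar treatment
(lithium, divalproex/valproate, valpromide) during the study year, are
excluded from every method.

Window semantics: "last *k* calendar years" means the *k* calendar years
ending at and including the study year, so the 2-year window is
{year−1, year} and the 5-year window is {year−4, …, year}.  Stays are dated
by their admission year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .code_sets import CodeSet, default_registry
from .data_model import ClaimsBundle

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "SUB_SOURCE_LABELS",
    "antidepressant_users",
    "select_method_a",
    "select_method_b",
    "select_method_c",
    "select_method_d",
    "select_method_e",
    "bipolar_exclusion",
    "run_selection",
]

#: sub-source labels in decreasing order of reliability (report row order)
SUB_SOURCE_LABELS = [
    "A",
    "B_psy_1y",
    "B_gen_principal_1y",
    "B_psy_2y",
    "B_gen_principal_2y",
    "C_psy_history",
    "C_gen_principal_history",
    "D_1y",
    "D_2y",
    "E",
]

IdSet = frozenset


@dataclass(frozen=True)
class SelectionConfig:
    """Tunable thresholds and code sets for the selection rules.

    ``ad_min_dispensings`` (default 3) counts *distinct dispensing dates* in
    the study year when ``distinct_dates`` is true — an antidepressant
    prescription is typically valid one month, so distinct dates approximate
    distinct reimbursement events.  ``bipolar_drug_min_dispensings`` defaults
    to 1 (the exclusion should be sensitive) and is counted over the study
    year only.
    """

    ad_min_dispensings: int = 3
    distinct_dates: bool = True
    bipolar_drug_min_dispensings: int = 1
    registry: dict[str, CodeSet] = field(default_factory=default_registry)


@dataclass(frozen=True)
class SelectionResult:
    """Per-sub-source beneficiary-id sets after the bipolar exclusion."""

    A: IdSet
    B_psy_1y: IdSet
    B_gen_principal_1y: IdSet
    B_psy_2y: IdSet
    B_gen_principal_2y: IdSet
    C_psy_history: IdSet
    C_gen_principal_history: IdSet
    D_1y: IdSet
    D_2y: IdSet
    E: IdSet
    excluded_bipolar: IdSet
    denominator_count: int
    #: raw 5-year stay-history sets (no treatment condition), after exclusion;
    #: these are the supersets in the 1y ⊆ 2y ⊆ 5y nesting chain
    psy_stay_history_5y: IdSet = frozenset()
    gen_principal_stay_history_5y: IdSet = frozenset()

    def sets(self) -> dict[str, IdSet]:
        """The ten sub-source sets keyed by label, in reliability order."""
        return {label: getattr(self, label) for label in SUB_SOURCE_LABELS}

    def method_sets(self) -> dict[str, IdSet]:
        """Aggregate method-level sets (B and C over their 2-year/5-year spans)."""
        return {
            "A": self.A,
            "B": self.B_psy_2y | self.B_gen_principal_2y,
            "C": self.C_psy_history | self.C_gen_principal_history,
            "D": self.D_2y,
            "E": self.E,
        }


# ---------------------------------------------------------------------------
# vectorised code matching over table columns
# ---------------------------------------------------------------------------

def _norm(codes: pd.Series) -> pd.Series:
    return codes.fillna("").astype(str).str.replace(".", "", regex=False).str.strip().str.upper()


def _match(codes: pd.Series, cs: CodeSet) -> pd.Series:
    if len(codes) == 0:
        return pd.Series(dtype=bool)
    s = _norm(codes)
    hit = s.str.startswith(tuple(cs.include_prefixes))
    if cs.exclude_prefixes:
        hit &= ~s.str.startswith(tuple(cs.exclude_prefixes))
    return hit


def _stay_frame(bundle: ClaimsBundle, cs: CodeSet) -> pd.DataFrame:
    """Per-stay summary: admission year, type, and whether the code set is hit
    in principal / any associated position."""
    stays = bundle.hospital_stays
    if len(stays) == 0:
        return pd.DataFrame(
            columns=["beneficiary_id", "year", "hospital_type", "principal", "associated"]
        )
    principal = _match(stays["principal_dx"], cs)
    toks = stays["associated_dx"].str.split(";")
    exploded = pd.DataFrame(
        {"i": stays.index.repeat(toks.str.len().fillna(0).astype(int)),
         "tok": [t for lst in toks for t in (lst or [])]}
    )
    exploded = exploded[exploded["tok"] != ""]
    assoc_hit = pd.Series(False, index=stays.index)
    if len(exploded):
        hits = exploded[_match(exploded["tok"], cs).to_numpy()]
        assoc_hit[hits["i"].unique()] = True
    return pd.DataFrame(
        {
            "beneficiary_id": stays["beneficiary_id"],
            "year": stays["admission_date"].dt.year,
            "hospital_type": stays["hospital_type"],
            "principal": principal,
            "associated": assoc_hit,
        }
    )


def _window(study_year: int, window_years: int) -> range:
    return range(study_year - window_years + 1, study_year + 1)


# ---------------------------------------------------------------------------
# individual rules
# ---------------------------------------------------------------------------

def antidepressant_users(
    bundle: ClaimsBundle, config: SelectionConfig | None = None
) -> IdSet:
    """Ids with ≥3 antidepressant dispensings on distinct dates in the study year."""
    config = config or SelectionConfig()
    disp = bundle.dispensings
    if len(disp) == 0:
        return frozenset()
    cs = config.registry["ANTIDEPRESSANT"]
    mask = _match(disp["atc"], cs) & (disp["date"].dt.year == bundle.study_year)
    hits = disp[mask.to_numpy()]
    if config.distinct_dates:
        counts = hits.groupby("beneficiary_id")["date"].nunique()
    else:
        counts = hits.groupby("beneficiary_id")["date"].size()
    return frozenset(counts.index[counts >= config.ad_min_dispensings])


def select_method_a(bundle: ClaimsBundle, config: SelectionConfig | None = None) -> IdSet:
    """Active full coverage (ALD) for depression overlapping the study year."""
    config = config or SelectionConfig()
    ald = bundle.ald_episodes
    if len(ald) == 0:
        return frozenset()
    cs = config.registry["DEPRESSION"]
    year_start = pd.Timestamp(bundle.study_year, 1, 1)
    year_end = pd.Timestamp(bundle.study_year, 12, 31)
    active = (ald["start_date"] <= year_end) & (
        ald["end_date"].isna() | (ald["end_date"] >= year_start)
    )
    mask = _match(ald["icd10"], cs) & active
    return frozenset(ald.loc[mask.to_numpy(), "beneficiary_id"])


def _b_like_sets(stay_frame: pd.DataFrame, years: range) -> tuple[IdSet, IdSet]:
    in_win = stay_frame["year"].isin(years)
    psy = stay_frame["hospital_type"].eq("psychiatric") & (
        stay_frame["principal"] | stay_frame["associated"]
    )
    gen_principal = stay_frame["hospital_type"].eq("general") & stay_frame["principal"]
    return (
        frozenset(stay_frame.loc[in_win & psy, "beneficiary_id"]),
        frozenset(stay_frame.loc[in_win & gen_principal, "beneficiary_id"]),
    )


def select_method_b(
    bundle: ClaimsBundle, window_years: int, config: SelectionConfig | None = None
) -> tuple[IdSet, IdSet]:
    """(psychiatric, general-principal) sets over a 1- or 2-year window."""
    if window_years not in (1, 2):
        raise ValueError(f"window_years must be 1 or 2, got {window_years}")
    config = config or SelectionConfig()
    sf = _stay_frame(bundle, config.registry["DEPRESSION"])
    return _b_like_sets(sf, _window(bundle.study_year, window_years))


def select_method_c(
    bundle: ClaimsBundle, config: SelectionConfig | None = None
) -> tuple[IdSet, IdSet]:
    """(psychiatric-history, general-principal-history) sets: treated + 5-year stay."""
    config = config or SelectionConfig()
    users = antidepressant_users(bundle, config)
    sf = _stay_frame(bundle, config.registry["DEPRESSION"])
    psy_hist, gen_hist = _b_like_sets(sf, _window(bundle.study_year, 5))
    return users & psy_hist, users & gen_hist


def select_method_d(
    bundle: ClaimsBundle, window_years: int, config: SelectionConfig | None = None
) -> IdSet:
    """General-hospital stays with depression in *associated* position only."""
    if window_years not in (1, 2):
        raise ValueError(f"window_years must be 1 or 2, got {window_years}")
    config = config or SelectionConfig()
    sf = _stay_frame(bundle, config.registry["DEPRESSION"])
    in_win = sf["year"].isin(_window(bundle.study_year, window_years))
    mask = in_win & sf["hospital_type"].eq("general") & sf["associated"]
    return frozenset(sf.loc[mask, "beneficiary_id"])


def select_method_e(bundle: ClaimsBundle, config: SelectionConfig | None = None) -> IdSet:
    """Treated + general-hospital associated-diagnosis stay in the last 5 years."""
    config = config or SelectionConfig()
    users = antidepressant_users(bundle, config)
    sf = _stay_frame(bundle, config.registry["DEPRESSION"])
    in_win = sf["year"].isin(_window(bundle.study_year, 5))
    mask = in_win & sf["hospital_type"].eq("general") & sf["associated"]
    return users & frozenset(sf.loc[mask, "beneficiary_id"])


def bipolar_exclusion(bundle: ClaimsBundle, config: SelectionConfig | None = None) -> IdSet:
    """Ids with a bipolar hospital diagnosis in the last 5 years or a specific
    bipolar treatment during the study year (both hospital types, both
    diagnosis positions — the broadest diagnostic net)."""
    config = config or SelectionConfig()
    sf = _stay_frame(bundle, config.registry["BIPOLAR_DX"])
    in_win = sf["year"].isin(_window(bundle.study_year, 5))
    by_dx = frozenset(sf.loc[in_win & (sf["principal"] | sf["associated"]), "beneficiary_id"])

    disp = bundle.dispensings
    by_drug: IdSet = frozenset()
    if len(disp):
        mask = _match(disp["atc"], config.registry["BIPOLAR_DRUG"]) & (
            disp["date"].dt.year == bundle.study_year
        )
        counts = disp[mask.to_numpy()].groupby("beneficiary_id").size()
        by_drug = frozenset(counts.index[counts >= config.bipolar_drug_min_dispensings])
    return by_dx | by_drug


def run_selection(
    bundle: ClaimsBundle, config: SelectionConfig | None = None
) -> SelectionResult:
    """Run every method, then subtract the bipolar exclusion from each set."""
    config = config or SelectionConfig()
    excluded = bipolar_exclusion(bundle, config)

    a = select_method_a(bundle, config)
    b_psy_1, b_gen_1 = select_method_b(bundle, 1, config)
    b_psy_2, b_gen_2 = select_method_b(bundle, 2, config)
    c_psy, c_gen = select_method_c(bundle, config)
    d_1 = select_method_d(bundle, 1, config)
    d_2 = select_method_d(bundle, 2, config)
    e = select_method_e(bundle, config)

    sf = _stay_frame(bundle, config.registry["DEPRESSION"])
    psy_hist, gen_hist = _b_like_sets(sf, _window(bundle.study_year, 5))

    return SelectionResult(
        A=a - excluded,
        B_psy_1y=b_psy_1 - excluded,
        B_gen_principal_1y=b_gen_1 - excluded,
        B_psy_2y=b_psy_2 - excluded,
        B_gen_principal_2y=b_gen_2 - excluded,
        C_psy_history=c_psy - excluded,
        C_gen_principal_history=c_gen - excluded,
        D_1y=d_1 - excluded,
        D_2y=d_2 - excluded,
        E=e - excluded,
        excluded_bipolar=excluded,
        denominator_count=len(bundle.beneficiaries),
        psy_stay_history_5y=psy_hist - excluded,
        gen_principal_stay_history_5y=gen_hist - excluded,
    )
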