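"""Independent per-individual rule evaluator used as the selection oracle.

This is a deliberately naive, straight-line re-implementation of each
textual selection rule: plain-Python loops over individuals and their
records, with the code lists written out inline.  It shares no matching or
windowing code with the vectorised pipeline, so agreement between the two is
a meaningful check.
"""

from __future__ import annotations

import pandas as pd

DEP_PREFIXES = ("F32", "F33", "F34", "F35", "F36", "F37", "F38", "F39")
BIPOLAR_PREFIXES = ("F30", "F31")
BIPOLAR_DRUGS = ("N05AN01", "N03AG01", "N03AG02")


def _norm(code: str) -> str:
    return str(code).replace(".", "").strip().upper()


def _is_dep(code: str) -> bool:
    return _norm(code).startswith(DEP_PREFIXES)


def _is_bipolar_dx(code: str) -> bool:
    return _norm(code).startswith(BIPOLAR_PREFIXES)


def _is_antidepressant(atc: str) -> bool:
    a = _norm(atc)
    return a.startswith("N06A") and not a.startswith("N06AX01")


def _records_by_person(bundle):
    """Plain-Python per-person record lists."""
    people = {pid: {"ald": [], "stays": [], "disp": []} for pid in bundle.beneficiaries["id"]}
    for rec in bundle.ald_episodes.to_dict("records"):
        people[rec["beneficiary_id"]]["ald"].append(rec)
    for rec in bundle.hospital_stays.to_dict("records"):
        rec = dict(rec)
        rec["assoc_list"] = [c for c in str(rec["associated_dx"]).split(";") if c]
        people[rec["beneficiary_id"]]["stays"].append(rec)
    for rec in bundle.dispensings.to_dict("records"):
        people[rec["beneficiary_id"]]["disp"].append(rec)
    return people


def oracle_selection(bundle) -> dict[str, frozenset]:
    """Evaluate every selection rule person by person; returns the ten
    post-exclusion sub-source sets plus the exclusion set."""
    year = bundle.study_year
    people = _records_by_person(bundle)

    raw: dict[str, set] = {
        label: set()
        for label in [
            "A", "B_psy_1y", "B_gen_principal_1y", "B_psy_2y", "B_gen_principal_2y",
            "C_psy_history", "C_gen_principal_history", "D_1y", "D_2y", "E",
        ]
    }
    excluded: set = set()

    for pid, rec in people.items():
        # treatment: >= 3 antidepressant dispensings on distinct dates, study year
        ad_dates = set()
        for d in rec["disp"]:
            if d["date"].year == year and _is_antidepressant(d["atc"]):
                ad_dates.add(d["date"])
        treated = len(ad_dates) >= 3

        # bipolar exclusion: hospital F30/F31 in last 5 calendar years (any
        # type, any position) or >= 1 specific bipolar drug in the study year
        bipolar = False
        for s in rec["stays"]:
            if year - 4 <= s["admission_date"].year <= year:
                if _is_bipolar_dx(s["principal_dx"]) or any(
                    _is_bipolar_dx(c) for c in s["assoc_list"]
                ):
                    bipolar = True
        for d in rec["disp"]:
            if d["date"].year == year and _norm(d["atc"]).startswith(BIPOLAR_DRUGS):
                bipolar = True
        if bipolar:
            excluded.add(pid)

        # method A: depression ALD episode overlapping the study year
        for ep in rec["ald"]:
            if not _is_dep(ep["icd10"]):
                continue
            starts_ok = ep["start_date"] <= pd.Timestamp(year, 12, 31)
            ends_ok = pd.isna(ep["end_date"]) or ep["end_date"] >= pd.Timestamp(year, 1, 1)
            if starts_ok and ends_ok:
                raw["A"].add(pid)

        # hospital-stay rules, per window
        psy_years = []
        gen_principal_years = []
        gen_assoc_years = []
        for s in rec["stays"]:
            ay = s["admission_date"].year
            dep_principal = _is_dep(s["principal_dx"])
            dep_assoc = any(_is_dep(c) for c in s["assoc_list"])
            if s["hospital_type"] == "psychiatric" and (dep_principal or dep_assoc):
                psy_years.append(ay)
            if s["hospital_type"] == "general" and dep_principal:
                gen_principal_years.append(ay)
            if s["hospital_type"] == "general" and dep_assoc:
                gen_assoc_years.append(ay)

        def in_window(years_list, w):
            return any(year - w + 1 <= ay <= year for ay in years_list)

        if in_window(psy_years, 1):
            raw["B_psy_1y"].add(pid)
        if in_window(psy_years, 2):
            raw["B_psy_2y"].add(pid)
        if in_window(gen_principal_years, 1):
            raw["B_gen_principal_1y"].add(pid)
        if in_window(gen_principal_years, 2):
            raw["B_gen_principal_2y"].add(pid)
        if treated and in_window(psy_years, 5):
            raw["C_psy_history"].add(pid)
        if treated and in_window(gen_principal_years, 5):
            raw["C_gen_principal_history"].add(pid)
        if in_window(gen_assoc_years, 1):
            raw["D_1y"].add(pid)
        if in_window(gen_assoc_years, 2):
            raw["D_2y"].add(pid)
        if treated and in_window(gen_assoc_years, 5):
            raw["E"].add(pid)

    out = {label: frozenset(ids - excluded) for label, ids in raw.items()}
    out["excluded_bipolar"] = frozenset(excluded)
    return out


def oracle_venn(a, b, c) -> dict[str, int]:
    """Region counts by per-element membership-pattern tally."""
    counts = {k: 0 for k in ("100", "010", "001", "110", "101", "011", "111")}
    for x in set(a) | set(b) | set(c):
        key = f"{int(x in a)}{int(x in b)}{int(x in c)}"
        counts[key] += 1
    return counts
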