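"""Relational claims schema: in-memory container, delimited-text I/O, validation.

The pipeline operates on four linked tables emulating a national
health-insurance claims extract:

* ``beneficiaries`` — one row per insured person: demographics, vital status,
  means-tested coverage (CMUC), pre-computed comorbidity flags and annual
  reimbursed amounts (euros) for the study year.
* ``ald_episodes`` — long-term-condition (ALD) full-coverage episodes, each
  carrying the qualifying ICD-10 code and a start/end date (open end = still
  active).
* ``hospital_stays`` — inpatient stays with hospital type (psychiatric or
  general), an ICD-10 principal diagnosis and zero or more associated
  diagnoses.
* ``dispensings`` — drug dispensings with ATC code and date.

All window logic downstream operates on calendar years extracted from ISO
dates; a stay belongs to the calendar year of its *admission* date.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClaimsBundle",
    "Violation",
    "BundleReadError",
    "BundleValidationError",
    "read_bundle",
    "write_bundle",
    "validate_bundle",
    "empty_bundle",
    "COMORBIDITY_NAMES",
    "COST_NAMES",
    "TABLE_FILES",
]

COMORBIDITY_NAMES = (
    "cardiovascular",
    "diabetes",
    "cancer",
    "neurological",
    "inflammatory_hiv",
    "eskd",
    "liver_pancreas",
)

COST_NAMES = ("ambulatory", "pharma", "hospital", "sick_leave", "disability")

BENEFICIARY_COLUMNS = (
    ["id", "sex", "birth_year", "death_date", "cmuc"]
    + [f"comorb_{c}" for c in COMORBIDITY_NAMES]
    + [f"cost_{c}" for c in COST_NAMES]
)
ALD_COLUMNS = ["beneficiary_id", "icd10", "start_date", "end_date"]
STAY_COLUMNS = [
    "beneficiary_id",
    "admission_date",
    "hospital_type",
    "principal_dx",
    "associated_dx",
]
DISPENSING_COLUMNS = ["beneficiary_id", "date", "atc"]

#: canonical file name for each table inside a bundle directory
TABLE_FILES = {
    "beneficiaries": "beneficiaries.csv",
    "ald_episodes": "ald.csv",
    "hospital_stays": "stays.csv",
    "dispensings": "dispensings.csv",
}

_DATE_COLUMNS = {
    "beneficiaries": ["death_date"],
    "ald_episodes": ["start_date", "end_date"],
    "hospital_stays": ["admission_date"],
    "dispensings": ["date"],
}
_BOOL_COLUMNS = ["cmuc"] + [f"comorb_{c}" for c in COMORBIDITY_NAMES]


class BundleReadError(Exception):
    """A structural problem (missing file/column, unparseable value) while reading."""


class BundleValidationError(Exception):
    """Raised by :func:`read_bundle` when the parsed bundle violates invariants."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        lines = "\n".join(str(v) for v in violations[:20])
        extra = "" if len(violations) <= 20 else f"\n... and {len(violations) - 20} more"
        super().__init__(f"{len(violations)} invariant violation(s):\n{lines}{extra}")


@dataclass(frozen=True)
class Violation:
    """One invariant violation, located by table name and 0-based row index."""

    table: str
    row: int | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f"{self.table}[{self.row}]" if self.row is not None else self.table
        return f"{where}: {self.message}"


@dataclass
class ClaimsBundle:
    """The four claims tables plus the study year — the input of every stage."""

    beneficiaries: pd.DataFrame
    ald_episodes: pd.DataFrame
    hospital_stays: pd.DataFrame
    dispensings: pd.DataFrame
    study_year: int
    meta: dict = field(default_factory=dict, compare=False)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "beneficiaries": self.beneficiaries,
            "ald_episodes": self.ald_episodes,
            "hospital_stays": self.hospital_stays,
            "dispensings": self.dispensings,
        }

    @property
    def beneficiary_ids(self) -> frozenset[str]:
        return frozenset(self.beneficiaries["id"])


def _empty_table(columns: list[str], table: str) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in columns})
    return _canonical(df, table)


def empty_bundle(study_year: int) -> ClaimsBundle:
    """A valid bundle with four empty tables."""
    return ClaimsBundle(
        beneficiaries=_empty_table(BENEFICIARY_COLUMNS, "beneficiaries"),
        ald_episodes=_empty_table(ALD_COLUMNS, "ald_episodes"),
        hospital_stays=_empty_table(STAY_COLUMNS, "hospital_stays"),
        dispensings=_empty_table(DISPENSING_COLUMNS, "dispensings"),
        study_year=study_year,
    )


def _canonical(df: pd.DataFrame, table: str) -> pd.DataFrame:
    """Coerce a raw table to canonical dtypes (dates, bools, numerics, strings)."""
    df = df.copy().reset_index(drop=True)
    for col in _DATE_COLUMNS[table]:
        if not pd.api.types.is_datetime64_any_dtype(df[col]):
            df[col] = pd.to_datetime(df[col], errors="raise")
    if table == "beneficiaries":
        for col in _BOOL_COLUMNS:
            df[col] = df[col].astype(int).astype(bool)
        df["birth_year"] = df["birth_year"].astype(np.int64)
        for c in COST_NAMES:
            df[f"cost_{c}"] = df[f"cost_{c}"].astype(float)
        df["id"] = df["id"].astype(str)
        df["sex"] = df["sex"].astype(str)
    else:
        for col in df.columns:
            if col not in _DATE_COLUMNS[table]:
                df[col] = df[col].fillna("").astype(str)
    return df


def _read_table(path: Path, table: str, columns: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise BundleReadError(f"{table}: file not found: {path}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in raw.columns]
    if missing:
        raise BundleReadError(f"{table}: missing column(s) {missing} in {path}")
    raw = raw[columns]
    for col in _DATE_COLUMNS[table]:
        raw[col] = raw[col].replace("", None)
    for col in _DATE_COLUMNS[table]:
        parsed = pd.to_datetime(raw[col], format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & raw[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise BundleReadError(
                f"{table}: unparseable date {raw[col][row]!r} in column "
                f"{col!r} at row {row}"
            )
        raw[col] = parsed
    if table == "beneficiaries":
        for col in _BOOL_COLUMNS + ["birth_year"] + [f"cost_{c}" for c in COST_NAMES]:
            try:
                raw[col] = pd.to_numeric(raw[col])
            except ValueError as exc:
                raise BundleReadError(f"{table}: unparseable column {col!r}: {exc}")
    return _canonical(raw, table)


def read_bundle(
    directory: str | Path, study_year: int, *, validate: bool = True
) -> ClaimsBundle:
    """Read the four CSV tables from ``directory`` and return a validated bundle.

    Raises :class:`BundleReadError` for structural problems (missing file or
    column, unparseable date or number) and :class:`BundleValidationError`
    when referential or temporal invariants fail; both name the table and row.
    Row order in the files never affects downstream results.
    """
    directory = Path(directory)
    bundle = ClaimsBundle(
        beneficiaries=_read_table(
            directory / TABLE_FILES["beneficiaries"], "beneficiaries", BENEFICIARY_COLUMNS
        ),
        ald_episodes=_read_table(
            directory / TABLE_FILES["ald_episodes"], "ald_episodes", ALD_COLUMNS
        ),
        hospital_stays=_read_table(
            directory / TABLE_FILES["hospital_stays"], "hospital_stays", STAY_COLUMNS
        ),
        dispensings=_read_table(
            directory / TABLE_FILES["dispensings"], "dispensings", DISPENSING_COLUMNS
        ),
        study_year=study_year,
    )
    if validate:
        violations = validate_bundle(bundle)
        if violations:
            raise BundleValidationError(violations)
    return bundle


def _fmt_dates(df: pd.DataFrame, table: str) -> pd.DataFrame:
    out = df.copy()
    for col in _DATE_COLUMNS[table]:
        out[col] = out[col].dt.strftime("%Y-%m-%d")
    return out


def write_bundle(bundle: ClaimsBundle, directory: str | Path) -> list[Path]:
    """Write the four tables as UTF-8 CSV files; returns the written paths.

    ``read_bundle(write_bundle(b))`` reproduces ``b`` field for field
    (booleans serialise as 0/1, open dates as empty fields).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for table, df in bundle.tables().items():
        out = _fmt_dates(df, table)
        if table == "beneficiaries":
            for col in _BOOL_COLUMNS:
                out[col] = out[col].astype(int)
        path = directory / TABLE_FILES[table]
        out.to_csv(path, index=False)
        paths.append(path)
    return paths


def validate_bundle(bundle: ClaimsBundle) -> list[Violation]:
    """Check every schema invariant; an empty list means the bundle is valid.

    Violations are data, not exceptions: referential integrity (foreign keys),
    uniqueness of beneficiary ids, temporal sanity (birth before death and
    before the study year, episode end after start), non-negative costs,
    non-empty diagnosis and drug codes, and recognised categorical values.
    """
    v: list[Violation] = []
    ben = bundle.beneficiaries
    year = bundle.study_year

    if not (1000 <= year <= 9999):
        v.append(Violation("bundle", None, f"study_year {year} is not a 4-digit year"))

    dup = ben["id"].duplicated()
    for row in ben.index[dup]:
        v.append(Violation("beneficiaries", int(row), f"duplicate id {ben['id'][row]!r}"))
    bad_sex = ~ben["sex"].isin(["male", "female"])
    for row in ben.index[bad_sex]:
        v.append(Violation("beneficiaries", int(row), f"unknown sex {ben['sex'][row]!r}"))
    late = ben["birth_year"] > year
    for row in ben.index[late]:
        v.append(
            Violation("beneficiaries", int(row), f"birth_year {ben['birth_year'][row]} after study year {year}")
        )
    died_early = ben["death_date"].notna() & (ben["death_date"].dt.year < ben["birth_year"])
    for row in ben.index[died_early]:
        v.append(Violation("beneficiaries", int(row), "death_date before birth_year"))
    for c in COST_NAMES:
        neg = ben[f"cost_{c}"] < 0
        for row in ben.index[neg]:
            v.append(Violation("beneficiaries", int(row), f"negative cost_{c}"))

    ids = set(ben["id"])
    for table, df, key in [
        ("ald_episodes", bundle.ald_episodes, "beneficiary_id"),
        ("hospital_stays", bundle.hospital_stays, "beneficiary_id"),
        ("dispensings", bundle.dispensings, "beneficiary_id"),
    ]:
        dangling = ~df[key].isin(ids)
        for row in df.index[dangling]:
            v.append(Violation(table, int(row), f"unknown beneficiary_id {df[key][row]!r}"))

    ald = bundle.ald_episodes
    bad_span = ald["end_date"].notna() & (ald["end_date"] < ald["start_date"])
    for row in ald.index[bad_span]:
        v.append(Violation("ald_episodes", int(row), "end_date before start_date"))
    for row in ald.index[ald["icd10"] == ""]:
        v.append(Violation("ald_episodes", int(row), "empty icd10 code"))

    stays = bundle.hospital_stays
    for row in stays.index[stays["principal_dx"] == ""]:
        v.append(Violation("hospital_stays", int(row), "empty principal_dx"))
    bad_type = ~stays["hospital_type"].isin(["psychiatric", "general"])
    for row in stays.index[bad_type]:
        v.append(
            Violation("hospital_stays", int(row), f"unknown hospital_type {stays['hospital_type'][row]!r}")
        )

    disp = bundle.dispensings
    for row in disp.index[disp["atc"] == ""]:
        v.append(Violation("dispensings", int(row), "empty atc code"))

    return sorted(v, key=lambda x: (x.table, -1 if x.row is None else x.row))


def split_associated(series: pd.Series) -> pd.Series:
    """Split the semicolon-joined ``associated_dx`` column into lists."""
    return series.map(lambda s: [c for c in s.split(";") if c] if s else [])


def bundle_equal(a: ClaimsBundle, b: ClaimsBundle) -> bool:
    """Field-for-field equality of two bundles (ignoring metadata)."""
    if a.study_year != b.study_year:
        return False
    for (ta, dfa), dfb in zip(a.tables().items(), b.tables().values()):
        try:
            pd.testing.assert_frame_equal(dfa, dfb, check_dtype=False)
        except AssertionError:
            return False
    return True


def row_shuffled(bundle: ClaimsBundle, seed: int) -> ClaimsBundle:
    """A copy of the bundle with every table's rows permuted (for invariance tests)."""
    rng = np.random.default_rng(seed)
    kwargs = {}
    for table, df in bundle.tables().items():
        perm = rng.permutation(len(df))
        kwargs[table] = df.iloc[perm].reset_index(drop=True)
    return dataclasses.replace(bundle, **kwargs, meta=dict(bundle.meta))
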