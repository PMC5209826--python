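"""Synthetic claims-bundle generator with controllable selection structure.

Real national claims extracts are confidential, so every pipeline stage is
exercised on synthetic bundles whose *selection-relevant* structure is
controllable and solvable in closed form:

* each person independently draws, per hospital-stay source (psychiatric
  depression stay; general stay with principal depression diagnosis; general
  stay with associated depression diagnosis), a recency category — none /
  study year / previous year / 2–4 years back;
* antidepressant treatment (≥3 dispensings on distinct dates in the study
  year) is drawn conditionally on stay recency, which is the lever that
  controls the overlap between recent-hospitalisation selection and
  treatment-plus-history selection;
* long-term-condition (ALD) full coverage for depression is drawn with an
  elevated probability for persons who have any stay structure, which
  controls the overlap of the full-coverage source with the others;
* a small independent fraction is marked bipolar and receives a bipolar
  hospital diagnosis and/or a specific bipolar-treatment dispensing (and, by
  independence, often depression-like records too) — exercising the
  exclusion rule;
* death probability is elevated for persons whose only marker is a general
  hospital associated diagnosis, reproducing the mortality contrast between
  that stratum and the more reliable sources.

:func:`calibrated_params` calibrates the per-source probabilities so that
each sub-source's expected post-exclusion selected fraction equals the
published population fractions (counts over a 58,753,200 denominator), and
solves the recent-stay treatment probability by bisection so the expected
multi-source overlap among the three aggregate methods is 16%.
:func:`expected_selection_fractions` returns those expectations by exact
enumeration of the latent structure, for calibration tests.

Noise realism (records that must *not* select anyone): sub-threshold
antidepressant use, non-depression ALD episodes, depression ALD episodes
that expired before the study year, non-psychiatric hospital noise stays,
and non-antidepressant psychotropic dispensings for profiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import (
    ALD_COLUMNS,
    BENEFICIARY_COLUMNS,
    COMORBIDITY_NAMES,
    COST_NAMES,
    DISPENSING_COLUMNS,
    STAY_COLUMNS,
    ClaimsBundle,
    _canonical,
    empty_bundle,
)

__all__ = [
    "StayComponent",
    "GeneratorParams",
    "generate",
    "calibrated_params",
    "expected_selection_fractions",
    "expected_multi_source_fraction",
    "tiny_fixture",
    "PUBLISHED_DENOMINATOR",
    "PUBLISHED_SUB_SOURCE_COUNTS",
]

#: published study denominator (persons with ≥1 reimbursement, main scheme, 2012)
PUBLISHED_DENOMINATOR = 58_753_200

#: published per-sub-source set sizes; the 2-year entries are the aggregate
#: 2-year-window set sizes (the study's tables print previous-year-only
#: increments for those rows, but the sets themselves are windows)
PUBLISHED_SUB_SOURCE_COUNTS = {
    "A": 271_275,
    "B_psy_1y": 109_260,
    "B_gen_principal_1y": 34_630,
    "B_psy_2y": 179_470,
    "B_gen_principal_2y": 66_595,
    "C_psy_history": 137_110,
    "C_gen_principal_history": 51_420,
    "D_1y": 213_010,
    "D_2y": 340_270,
    "E": 266_890,
}

PUBLISHED_MULTI_SOURCE_FRACTION = 0.16

_DEP_ALD_CODES = ["F32", "F321", "F329", "F33", "F331", "F341"]
_DEP_STAY_CODES = ["F320", "F321", "F322", "F323", "F329", "F331", "F332", "F339", "F341"]
_OTHER_PSY_CODES = ["F419", "F410", "F609", "F431"]
_SOMATIC_CODES = ["I219", "I639", "C509", "C349", "J189", "E119", "S7200", "K703"]
_OTHER_ALD_CODES = ["E11", "C50", "I25", "G30", "J44"]
_AD_CODES = ["N06AB03", "N06AB06", "N06AX11", "N06AX16", "N06AA04", "N06AX21"]
_BIPOLAR_DX_CODES = ["F310", "F311", "F313", "F319", "F300"]
_BIPOLAR_DRUG_CODES = ["N05AN01", "N03AG01", "N03AG02"]
_CLASS_CODES = {
    "anxiolytic": ["N05BA01", "N05BA12", "N05BB01"],
    "hypnotic": ["N05CD06", "N05CF01", "N05CF02"],
    "neuroleptic": ["N05AH04", "N05AD01", "N05AX08"],
}


@dataclass(frozen=True)
class StayComponent:
    """Recency distribution of one stay source: study year / previous year /
    2–4 calendar years back (a person draws at most one stay per source)."""

    p_current: float
    p_previous: float
    p_history: float

    @property
    def p_recent(self) -> float:
        return self.p_current + self.p_previous

    @property
    def p_any(self) -> float:
        return self.p_current + self.p_previous + self.p_history


@dataclass(frozen=True)
class GeneratorParams:
    """Full parameterisation of the generator; see the module docstring.

    Probabilities for the stay components and for ALD are *conditional on the
    whole population* (bipolar persons draw them too — they are the
    contamination the exclusion removes), so the expected post-exclusion
    selected fraction carries a factor (1 − p_bipolar).
    """

    n: int
    psy: StayComponent
    gen_principal: StayComponent
    gen_associated: StayComponent
    p_ald_given_structure: float
    p_ald_baseline: float
    treat_recent: float
    treat_history: float
    study_year: int = 2012
    seed: int = 0
    treat_ald: float = 0.72
    treat_background: float = 0.05
    p_bipolar: float = 0.005
    history_year_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    #: annual death probability per mortality stratum; "gen_associated_only"
    #: is the general-hospital associated-diagnosis stratum with no other
    #: marker, whose excess mortality the cohort tables must reproduce
    death_rate_by_stratum: dict[str, float] = field(
        default_factory=lambda: {
            "gen_associated_only": 0.08,
            "other_selected": 0.025,
            "background": 0.009,
        }
    )
    age_by_stratum: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "ald": (58.0, 17.0),
            "psy": (50.0, 17.0),
            "gen_principal": (52.0, 18.0),
            "gen_associated": (61.0, 19.0),
            "background": (42.0, 23.0),
        }
    )
    male_frac_by_stratum: dict[str, float] = field(
        default_factory=lambda: {
            "ald": 0.28,
            "psy": 0.36,
            "gen_principal": 0.35,
            "gen_associated": 0.33,
            "background": 0.49,
        }
    )
    cmuc_rate_selected: float = 0.144
    cmuc_rate_background: float = 0.066
    comorbidity_rates: dict[str, float] = field(
        default_factory=lambda: {
            "cardiovascular": 0.149,
            "diabetes": 0.114,
            "cancer": 0.091,
            "neurological": 0.090,
            "inflammatory_hiv": 0.040,
            "eskd": 0.002,
            "liver_pancreas": 0.039,
        }
    )
    comorbidity_background_factor: float = 0.5
    comorbidity_gen_associated_factor: float = 2.0
    #: mean annual reimbursed euros per category (gamma-distributed draws)
    cost_means_selected: dict[str, float] = field(
        default_factory=lambda: {
            "ambulatory": 1739.0,
            "pharma": 1147.0,
            "hospital": 6795.0,
            "sick_leave": 799.0,
            "disability": 1068.0,
        }
    )
    cost_means_background: dict[str, float] = field(
        default_factory=lambda: {
            "ambulatory": 300.0,
            "pharma": 150.0,
            "hospital": 120.0,
            "sick_leave": 60.0,
            "disability": 10.0,
        }
    )
    psychotropic_class_rates_selected: dict[str, float] = field(
        default_factory=lambda: {"anxiolytic": 0.55, "neuroleptic": 0.20, "hypnotic": 0.30}
    )
    psychotropic_class_rate_background: float = 0.03
    p_subthreshold_ad: float = 0.03
    p_other_ald: float = 0.05
    p_expired_dep_ald: float = 0.002
    p_noise_stay: float = 0.01
    #: bipolar marker arms: P(stay marker), P(drug marker); at least one is forced
    p_bipolar_stay_marker: float = 0.7
    p_bipolar_drug_marker: float = 0.6

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if not (1000 <= self.study_year <= 9999):
            raise ValueError("study_year must be a 4-digit year")
        for name in ("psy", "gen_principal", "gen_associated"):
            comp: StayComponent = getattr(self, name)
            for p in (comp.p_current, comp.p_previous, comp.p_history):
                if not 0 <= p <= 1:
                    raise ValueError(f"{name}: probability out of [0,1]")
            if comp.p_any > 1:
                raise ValueError(f"{name}: category probabilities sum to >1")
        probs = [
            self.p_ald_given_structure, self.p_ald_baseline,
            self.treat_recent, self.treat_history, self.treat_ald,
            self.treat_background, self.p_bipolar,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("a probability parameter is out of [0,1]")
        if abs(sum(self.history_year_weights) - 1) > 1e-9:
            raise ValueError("history_year_weights must sum to 1")


# ---------------------------------------------------------------------------
# exact expectations over the latent structure
# ---------------------------------------------------------------------------

_CATS = ("none", "current", "previous", "history")


def _cat_probs(comp: StayComponent) -> dict[str, float]:
    return {
        "none": 1.0 - comp.p_any,
        "current": comp.p_current,
        "previous": comp.p_previous,
        "history": comp.p_history,
    }


def _enumerate_cells(params: GeneratorParams):
    """Yield (prob, psy_cat, gp_cat, ga_cat, ald, treat_prob) over the full
    latent joint distribution (conditional on the whole population; the
    bipolar factor is applied by the callers)."""
    psy_p = _cat_probs(params.psy)
    gp_p = _cat_probs(params.gen_principal)
    ga_p = _cat_probs(params.gen_associated)
    for pc in _CATS:
        for gc in _CATS:
            for ac in _CATS:
                base = psy_p[pc] * gp_p[gc] * ga_p[ac]
                if base == 0.0:
                    continue
                structure = not (pc == gc == ac == "none")
                p_ald = params.p_ald_given_structure if structure else params.p_ald_baseline
                recent = any(c in ("current", "previous") for c in (pc, gc, ac))
                hist = any(c == "history" for c in (pc, gc, ac))
                for ald in (True, False):
                    prob = base * (p_ald if ald else 1.0 - p_ald)
                    if prob == 0.0:
                        continue
                    if recent:
                        t = params.treat_recent
                    elif hist:
                        t = params.treat_history
                    elif ald:
                        t = params.treat_ald
                    else:
                        t = params.treat_background
                    yield prob, pc, gc, ac, ald, t


def expected_selection_fractions(params: GeneratorParams) -> dict[str, float]:
    """Expected post-exclusion selected fraction per sub-source, by exact
    enumeration of the latent joint distribution."""
    acc = {label: 0.0 for label in PUBLISHED_SUB_SOURCE_COUNTS}
    for prob, pc, gc, ac, ald, t in _enumerate_cells(params):
        if ald:
            acc["A"] += prob
        if pc == "current":
            acc["B_psy_1y"] += prob
        if pc in ("current", "previous"):
            acc["B_psy_2y"] += prob
        if gc == "current":
            acc["B_gen_principal_1y"] += prob
        if gc in ("current", "previous"):
            acc["B_gen_principal_2y"] += prob
        if pc != "none":
            acc["C_psy_history"] += prob * t
        if gc != "none":
            acc["C_gen_principal_history"] += prob * t
        if ac == "current":
            acc["D_1y"] += prob
        if ac in ("current", "previous"):
            acc["D_2y"] += prob
        if ac != "none":
            acc["E"] += prob * t
    scale = 1.0 - params.p_bipolar
    return {k: v * scale for k, v in acc.items()}


def expected_multi_source_fraction(params: GeneratorParams) -> float:
    """Expected fraction of the aggregate A ∪ B ∪ C union selected by more
    than one of the three methods (B over its 2-year window, C over the
    5-year history window), by exact enumeration."""
    union = 0.0
    multi = 0.0
    for prob, pc, gc, ac, ald, t in _enumerate_cells(params):
        in_b = pc in ("current", "previous") or gc in ("current", "previous")
        c_eligible = pc != "none" or gc != "none"
        deterministic = int(ald) + int(in_b)
        p_c = t if c_eligible else 0.0
        if deterministic >= 1:
            union += prob
        else:
            union += prob * p_c
        if deterministic >= 2:
            multi += prob
        elif deterministic == 1:
            multi += prob * p_c
    return multi / union if union else float("nan")


def calibrated_params(n: int, study_year: int = 2012, seed: int = 0) -> GeneratorParams:
    """Parameters calibrated to the published population structure.

    Per-source recency probabilities are set so each sub-source's expected
    selected fraction equals its published count over the 58,753,200
    denominator; the treatment probability given a recent stay is solved by
    bisection so the expected A/B/C multi-source overlap is 16%; history-
    stratum sizes then follow from the treated-with-history set sizes at a
    fixed high treatment probability (0.8 — persons selected via history are
    by definition still treated, so the stratum needs few untreated members).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    p_bip = 0.005
    s = 1.0 / (1.0 - p_bip)
    f = {k: v / PUBLISHED_DENOMINATOR * s for k, v in PUBLISHED_SUB_SOURCE_COUNTS.items()}
    t_hist = 0.8
    a1 = 0.10  # P(depression ALD | any stay structure): sets the A overlap

    recents = {
        "psy": (f["B_psy_1y"], f["B_psy_2y"] - f["B_psy_1y"], f["C_psy_history"]),
        "gen_principal": (
            f["B_gen_principal_1y"],
            f["B_gen_principal_2y"] - f["B_gen_principal_1y"],
            f["C_gen_principal_history"],
        ),
        "gen_associated": (f["D_1y"], f["D_2y"] - f["D_1y"], f["E"]),
    }

    def build(t_recent: float) -> GeneratorParams:
        comps = {}
        for name, (p_c, p_p, f_treated_any) in recents.items():
            h = (f_treated_any - t_recent * (p_c + p_p)) / t_hist
            comps[name] = StayComponent(p_current=p_c, p_previous=p_p, p_history=max(h, 0.0))
        p_struct = 1.0 - math.prod(1.0 - comps[k].p_any for k in comps)
        a0 = (f["A"] - a1 * p_struct) / (1.0 - p_struct)
        return GeneratorParams(
            n=n,
            study_year=study_year,
            seed=seed,
            psy=comps["psy"],
            gen_principal=comps["gen_principal"],
            gen_associated=comps["gen_associated"],
            p_ald_given_structure=a1,
            p_ald_baseline=a0,
            treat_recent=t_recent,
            treat_history=t_hist,
            p_bipolar=p_bip,
        )

    # expected multi-source overlap is monotone increasing in treat_recent
    t_max = min(ft / (pc + pp) for pc, pp, ft in recents.values()) - 1e-9
    lo, hi = 0.0, t_max
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if expected_multi_source_fraction(build(mid)) < PUBLISHED_MULTI_SOURCE_FRACTION:
            lo = mid
        else:
            hi = mid
    params = build((lo + hi) / 2.0)
    params.validate()
    return params


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _dates_in_year(rng: np.random.Generator, years: np.ndarray) -> pd.Series:
    """One uniform calendar date per entry of ``years`` (day 1–365)."""
    start = pd.to_datetime(pd.DataFrame({"year": years, "month": 1, "day": 1}))
    return start + pd.to_timedelta(rng.integers(0, 365, len(years)), unit="D")


def _distinct_dates(rng: np.random.Generator, year: int, k: int) -> list[pd.Timestamp]:
    offsets = rng.choice(365, size=k, replace=False)
    base = pd.Timestamp(year, 1, 1)
    return [base + pd.Timedelta(days=int(o)) for o in offsets]


def _draw_component(
    rng: np.random.Generator, comp: StayComponent, n: int, study_year: int,
    hist_weights: tuple[float, float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Returns (category codes 0=none/1=current/2=previous/3=history, stay year)."""
    u = rng.random(n)
    cat = np.zeros(n, dtype=np.int8)
    cat[u < comp.p_current] = 1
    cat[(u >= comp.p_current) & (u < comp.p_recent)] = 2
    cat[(u >= comp.p_recent) & (u < comp.p_any)] = 3
    year = np.full(n, -1, dtype=np.int64)
    year[cat == 1] = study_year
    year[cat == 2] = study_year - 1
    n_hist = int((cat == 3).sum())
    year[cat == 3] = rng.choice(
        [study_year - 2, study_year - 3, study_year - 4], size=n_hist, p=hist_weights
    )
    return cat, year


def generate(params: GeneratorParams) -> ClaimsBundle:
    """Draw a claims bundle from the latent structure; deterministic in
    (seed, params); the bundle always passes validation."""
    params.validate()
    y = params.study_year
    n = params.n
    if n == 0:
        b = empty_bundle(y)
        b.meta.update(seed=params.seed, generator="depclaims.synthetic")
        return b
    rng = np.random.default_rng(params.seed)
    ids = np.array([f"b{i:07d}" for i in range(n)])

    bipolar = rng.random(n) < params.p_bipolar
    psy_cat, psy_year = _draw_component(rng, params.psy, n, y, params.history_year_weights)
    gp_cat, gp_year = _draw_component(rng, params.gen_principal, n, y, params.history_year_weights)
    ga_cat, ga_year = _draw_component(rng, params.gen_associated, n, y, params.history_year_weights)

    structure = (psy_cat > 0) | (gp_cat > 0) | (ga_cat > 0)
    p_ald = np.where(structure, params.p_ald_given_structure, params.p_ald_baseline)
    ald = rng.random(n) < p_ald

    recent = (psy_cat == 1) | (psy_cat == 2) | (gp_cat == 1) | (gp_cat == 2) | (
        ga_cat == 1
    ) | (ga_cat == 2)
    hist_any = (psy_cat == 3) | (gp_cat == 3) | (ga_cat == 3)
    t_prob = np.where(
        recent,
        params.treat_recent,
        np.where(hist_any, params.treat_history,
                 np.where(ald, params.treat_ald, params.treat_background)),
    )
    treated = rng.random(n) < t_prob

    # demographic stratum: general-associated dominates (oldest, sickest),
    # then full coverage, then the psychiatric / general-principal strata
    stratum = np.full(n, "background", dtype=object)
    stratum[gp_cat > 0] = "gen_principal"
    stratum[psy_cat > 0] = "psy"
    stratum[ald] = "ald"
    stratum[ga_cat > 0] = "gen_associated"

    age = np.empty(n)
    male = np.empty(n, dtype=bool)
    for name, (mean, sd) in params.age_by_stratum.items():
        mask = stratum == name
        k = int(mask.sum())
        lo_age = 18.0 if name != "background" else 0.0
        age[mask] = np.clip(rng.normal(mean, sd, k), lo_age, 99.0)
        male[mask] = rng.random(k) < params.male_frac_by_stratum[name]
    birth_year = y - age.astype(np.int64)

    selected_like = structure | ald
    cmuc = rng.random(n) < np.where(
        selected_like, params.cmuc_rate_selected, params.cmuc_rate_background
    )

    ga_only = (ga_cat > 0) & ~((psy_cat > 0) | (gp_cat > 0) | ald)
    death_p = np.where(
        ga_only,
        params.death_rate_by_stratum["gen_associated_only"],
        np.where(selected_like, params.death_rate_by_stratum["other_selected"],
                 params.death_rate_by_stratum["background"]),
    )
    dies = rng.random(n) < death_p
    death_date = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    if dies.any():
        death_date[dies] = _dates_in_year(rng, np.full(int(dies.sum()), y)).to_numpy()

    comorb = {}
    for name in COMORBIDITY_NAMES:
        base = params.comorbidity_rates[name]
        rate = np.where(
            selected_like,
            np.where(ga_only, min(base * params.comorbidity_gen_associated_factor, 0.95), base),
            base * params.comorbidity_background_factor,
        )
        comorb[name] = rng.random(n) < rate

    costs = {}
    for cname in COST_NAMES:
        mean = np.where(
            selected_like,
            params.cost_means_selected[cname],
            params.cost_means_background[cname],
        )
        shape = 1.2
        costs[cname] = np.round(rng.gamma(shape, mean / shape, n), 2)

    beneficiaries = pd.DataFrame(
        {
            "id": ids,
            "sex": np.where(male, "male", "female"),
            "birth_year": birth_year,
            "death_date": death_date,
            "cmuc": cmuc,
            **{f"comorb_{k}": v for k, v in comorb.items()},
            **{f"cost_{k}": v for k, v in costs.items()},
        }
    )[BENEFICIARY_COLUMNS]

    # ---- ALD episodes -----------------------------------------------------
    ald_rows: list[dict] = []
    for i in np.flatnonzero(ald):
        start_year = int(rng.integers(y - 6, y + 1))
        start = pd.Timestamp(start_year, 1, 1) + pd.Timedelta(days=int(rng.integers(0, 365)))
        open_ended = rng.random() < 0.85
        end = pd.NaT
        if not open_ended:
            end_candidate = pd.Timestamp(y, 1, 1) + pd.Timedelta(days=int(rng.integers(0, 365)))
            end = max(start, end_candidate)
        ald_rows.append(
            dict(beneficiary_id=ids[i], icd10=str(rng.choice(_DEP_ALD_CODES)),
                 start_date=start, end_date=end)
        )
    expired = (~ald) & (rng.random(n) < params.p_expired_dep_ald)
    for i in np.flatnonzero(expired):
        start_year = int(rng.integers(y - 6, y - 2))
        end_year = int(rng.integers(y - 2, y))
        ald_rows.append(
            dict(
                beneficiary_id=ids[i], icd10=str(rng.choice(_DEP_ALD_CODES)),
                start_date=pd.Timestamp(start_year, 1, 1) + pd.Timedelta(days=int(rng.integers(0, 365))),
                end_date=pd.Timestamp(end_year, 12, 31),
            )
        )
    other_ald = rng.random(n) < params.p_other_ald
    for i in np.flatnonzero(other_ald):
        start_year = int(rng.integers(y - 8, y + 1))
        ald_rows.append(
            dict(
                beneficiary_id=ids[i], icd10=str(rng.choice(_OTHER_ALD_CODES)),
                start_date=pd.Timestamp(start_year, 1, 1) + pd.Timedelta(days=int(rng.integers(0, 365))),
                end_date=pd.NaT,
            )
        )

    # ---- hospital stays ---------------------------------------------------
    stay_rows: list[dict] = []

    def _stay_date(year: int) -> pd.Timestamp:
        return pd.Timestamp(year, 1, 1) + pd.Timedelta(days=int(rng.integers(0, 365)))

    for i in np.flatnonzero(psy_cat > 0):
        dep = str(rng.choice(_DEP_STAY_CODES))
        if rng.random() < 0.7:
            principal, associated = dep, ([str(rng.choice(_OTHER_PSY_CODES))] if rng.random() < 0.3 else [])
        else:
            principal, associated = str(rng.choice(_OTHER_PSY_CODES)), [dep]
        stay_rows.append(
            dict(beneficiary_id=ids[i], admission_date=_stay_date(int(psy_year[i])),
                 hospital_type="psychiatric", principal_dx=principal,
                 associated_dx=";".join(associated))
        )
    for i in np.flatnonzero(gp_cat > 0):
        associated = [str(rng.choice(_SOMATIC_CODES))] if rng.random() < 0.4 else []
        stay_rows.append(
            dict(beneficiary_id=ids[i], admission_date=_stay_date(int(gp_year[i])),
                 hospital_type="general", principal_dx=str(rng.choice(_DEP_STAY_CODES)),
                 associated_dx=";".join(associated))
        )
    for i in np.flatnonzero(ga_cat > 0):
        associated = [str(rng.choice(_DEP_STAY_CODES))]
        if rng.random() < 0.5:
            associated.append(str(rng.choice(_SOMATIC_CODES)))
        stay_rows.append(
            dict(beneficiary_id=ids[i], admission_date=_stay_date(int(ga_year[i])),
                 hospital_type="general", principal_dx=str(rng.choice(_SOMATIC_CODES)),
                 associated_dx=";".join(associated))
        )
    noise_stay = rng.random(n) < params.p_noise_stay
    for i in np.flatnonzero(noise_stay):
        stay_rows.append(
            dict(beneficiary_id=ids[i],
                 admission_date=_stay_date(int(rng.integers(y - 4, y + 1))),
                 hospital_type="general", principal_dx=str(rng.choice(_SOMATIC_CODES)),
                 associated_dx=""))

    # bipolar markers: at least one of (5-year hospital diagnosis, study-year
    # specific treatment) per flagged person
    bip_drug_rows: list[dict] = []
    for i in np.flatnonzero(bipolar):
        has_stay = rng.random() < params.p_bipolar_stay_marker
        has_drug = rng.random() < params.p_bipolar_drug_marker
        if not has_stay and not has_drug:
            has_stay = True
        if has_stay:
            year = int(rng.integers(y - 4, y + 1))
            htype = "psychiatric" if rng.random() < 0.6 else "general"
            code = str(rng.choice(_BIPOLAR_DX_CODES))
            if rng.random() < 0.5:
                principal, associated = code, []
            else:
                principal, associated = str(rng.choice(_SOMATIC_CODES)), [code]
            stay_rows.append(
                dict(beneficiary_id=ids[i], admission_date=_stay_date(year),
                     hospital_type=htype, principal_dx=principal,
                     associated_dx=";".join(associated))
            )
        if has_drug:
            for d in _distinct_dates(rng, y, int(rng.integers(1, 4))):
                bip_drug_rows.append(
                    dict(beneficiary_id=ids[i], date=d, atc=str(rng.choice(_BIPOLAR_DRUG_CODES)))
                )

    # ---- dispensings ------------------------------------------------------
    disp_rows: list[dict] = []
    for i in np.flatnonzero(treated):
        for d in _distinct_dates(rng, y, int(rng.integers(3, 9))):
            disp_rows.append(dict(beneficiary_id=ids[i], date=d, atc=str(rng.choice(_AD_CODES))))
    sub = (~treated) & (rng.random(n) < params.p_subthreshold_ad)
    for i in np.flatnonzero(sub):
        for d in _distinct_dates(rng, y, int(rng.integers(1, 3))):
            disp_rows.append(dict(beneficiary_id=ids[i], date=d, atc=str(rng.choice(_AD_CODES))))
    for cls, codes in _CLASS_CODES.items():
        rate_sel = params.psychotropic_class_rates_selected[cls]
        rate = np.where(selected_like, rate_sel, params.psychotropic_class_rate_background)
        takes = rng.random(n) < rate
        for i in np.flatnonzero(takes):
            for d in _distinct_dates(rng, y, int(rng.integers(3, 7))):
                disp_rows.append(dict(beneficiary_id=ids[i], date=d, atc=str(rng.choice(codes))))
    disp_rows.extend(bip_drug_rows)

    bundle = ClaimsBundle(
        beneficiaries=_canonical(beneficiaries, "beneficiaries"),
        ald_episodes=_canonical(
            pd.DataFrame(ald_rows, columns=ALD_COLUMNS), "ald_episodes"
        ),
        hospital_stays=_canonical(
            pd.DataFrame(stay_rows, columns=STAY_COLUMNS), "hospital_stays"
        ),
        dispensings=_canonical(
            pd.DataFrame(disp_rows, columns=DISPENSING_COLUMNS), "dispensings"
        ),
        study_year=y,
        meta=dict(seed=params.seed, generator="depclaims.synthetic"),
    )
    return bundle


# ---------------------------------------------------------------------------
# hand-designed 10-person fixture
# ---------------------------------------------------------------------------

def tiny_fixture(study_year: int = 2012) -> ClaimsBundle:
    """A deterministic 10-person bundle exercising every rule branch.

    Membership (study year 2012), enumerated by hand:

    ======  ==========================================================
    person  rule branch exercised
    ======  ==========================================================
    b01     A (open depression ALD from 2010); antidepressant user
    b02     expired depression ALD (ended 2011) — selected by nothing
    b03     B via psychiatric *associated* dx, study year; only 2
            dispensing dates (below treatment threshold)
    b04     B 2-year window (psychiatric stay 2011); 4 dispensings on
            only 2 distinct dates — not a treatment user
    b05     C psychiatric history at the inner window edge (2008 stay,
            associated dx) + treated
    b06     psychiatric stay 2007 — *outside* the 5-year window;
            treated but selected by nothing
    b07     B general-principal, study year + treated (also C gen);
            no associated depression dx, so not D
    b08     D (general stay, associated depression dx), untreated so
            not E; dies in the study year
    b09     E only (general associated stay 2008 + treated); dies the
            *following* year (must not count as in-year mortality)
    b10     bipolar exclusion, both arms: F31 associated dx on a 2009
            stay *and* a lithium dispensing in the study year; would
            otherwise qualify for B via a 2012 psychiatric stay
    ======  ==========================================================

    Costs are chosen so the whole-bundle totals per category are
    (946, 624, 3697, 435, 581), grand total 6283.
    """
    y = study_year
    if y != 2012:
        raise ValueError("the hand fixture is defined for study year 2012")

    ben = pd.DataFrame(
        [
            # id, sex, birth_year, death, cmuc, comorb..., costs...
            ("b01", "female", 1954, None, 0, 0, 0, 0, 0, 0, 0, 0, 100, 60, 0, 50, 0),
            ("b02", "male", 1980, None, 1, 0, 0, 0, 0, 0, 0, 0, 46, 24, 0, 35, 0),
            ("b03", "female", 1990, None, 1, 0, 0, 0, 0, 0, 0, 0, 100, 80, 500, 50, 81),
            ("b04", "male", 1967, None, 0, 0, 0, 0, 0, 0, 0, 0, 100, 60, 700, 100, 100),
            ("b05", "female", 1940, None, 0, 0, 0, 0, 1, 0, 0, 0, 100, 60, 0, 0, 100),
            ("b06", "male", 1985, None, 0, 0, 0, 0, 0, 0, 0, 0, 100, 60, 0, 100, 100),
            ("b07", "female", 1952, None, 0, 0, 0, 0, 0, 0, 0, 0, 100, 100, 800, 0, 100),
            ("b08", "male", 1937, "2012-09-01", 0, 1, 1, 0, 0, 0, 0, 0, 100, 60, 900, 0, 0),
            ("b09", "female", 1948, "2013-02-10", 0, 0, 0, 1, 0, 0, 0, 0, 100, 60, 400, 50, 100),
            ("b10", "male", 1977, None, 1, 0, 0, 0, 0, 0, 0, 0, 100, 60, 397, 50, 0),
        ],
        columns=BENEFICIARY_COLUMNS,
    )

    ald = pd.DataFrame(
        [
            ("b01", "F331", "2010-03-01", None),
            ("b02", "F32", "2008-01-01", "2011-06-30"),
        ],
        columns=ALD_COLUMNS,
    )

    stays = pd.DataFrame(
        [
            ("b03", "2012-05-10", "psychiatric", "F412", "F331"),
            ("b04", "2011-11-02", "psychiatric", "F329", ""),
            ("b05", "2008-09-12", "psychiatric", "F602", "F341"),
            ("b06", "2007-04-01", "psychiatric", "F339", ""),
            ("b07", "2012-02-20", "general", "F322", "I10"),
            ("b08", "2012-06-18", "general", "I638", "F330;E119"),
            ("b09", "2008-03-03", "general", "C509", "F331"),
            ("b10", "2012-04-04", "psychiatric", "F323", ""),
            ("b10", "2009-07-07", "general", "I10", "F310"),
        ],
        columns=STAY_COLUMNS,
    )

    def _ad(person, *dates):
        return [(person, d, code) for d, code in zip(dates, ["N06AB03", "N06AB06", "N06AX11", "N06AB03"])]

    disp_rows = []
    disp_rows += _ad("b01", "2012-01-15", "2012-04-20", "2012-09-03")
    disp_rows += _ad("b03", "2012-02-01", "2012-03-01")                      # 2 dates: below threshold
    disp_rows += [("b04", "2012-03-01", "N06AB03"), ("b04", "2012-03-01", "N06AB06"),
                  ("b04", "2012-07-15", "N06AX11"), ("b04", "2012-07-15", "N06AB03")]
    disp_rows += _ad("b05", "2012-01-05", "2012-05-05", "2012-10-05")
    disp_rows += _ad("b06", "2012-02-11", "2012-06-11", "2012-11-11")
    disp_rows += _ad("b07", "2012-03-09", "2012-07-09", "2012-12-09")
    disp_rows += _ad("b09", "2012-01-25", "2012-04-25", "2012-08-25")
    # profiling-only psychotropics
    disp_rows += [("b03", d, "N05BA01") for d in ("2012-02-02", "2012-05-02", "2012-08-02")]
    disp_rows += [("b05", d, "N05CD06") for d in ("2012-03-03", "2012-06-03", "2012-09-03")]
    disp_rows += [("b08", d, "N05AH04") for d in ("2012-01-04", "2012-04-04", "2012-07-04")]
    # bipolar drug arm for b10
    disp_rows += [("b10", "2012-05-06", "N05AN01")]
    disp = pd.DataFrame(disp_rows, columns=DISPENSING_COLUMNS)

    return ClaimsBundle(
        beneficiaries=_canonical(ben, "beneficiaries"),
        ald_episodes=_canonical(ald, "ald_episodes"),
        hospital_stays=_canonical(stays, "hospital_stays"),
        dispensings=_canonical(disp, "dispensings"),
        study_year=y,
        meta={"generator": "depclaims.tiny_fixture"},
    )


def scaled_params(params: GeneratorParams, n: int, seed: int | None = None) -> GeneratorParams:
    """Same structure at a different population size (and optionally seed)."""
    return replace(params, n=n, seed=params.seed if seed is None else seed)
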