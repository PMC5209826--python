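"""Cohort profiling against hand-computed fixture values and consistency laws."""

import pytest

from depclaims import (
    cmuc_rate_under60_pct,
    mortality_rate_pct,
    profile_cohort,
    run_selection,
)


def test_fixture_full_population_profile_matches_hand_computation(fixture_bundle, fixture_truth):
    truth = fixture_truth["full_population_profile"]
    prof = profile_cohort(fixture_bundle, fixture_bundle.beneficiary_ids)
    assert prof.n == truth["n"]
    assert prof.age_mean == pytest.approx(truth["age_mean"])
    assert prof.age_sd == pytest.approx(truth["age_sd"])
    assert (prof.age_iqr_low, prof.age_iqr_high) == (truth["age_iqr_low"], truth["age_iqr_high"])
    assert prof.pct_male == pytest.approx(truth["pct_male"])
    assert prof.pct_antidepressant == pytest.approx(truth["pct_antidepressant"])
    assert prof.pct_anxiolytic == pytest.approx(truth["pct_anxiolytic"])
    assert prof.pct_neuroleptic == pytest.approx(truth["pct_neuroleptic"])
    assert prof.pct_hypnotic == pytest.approx(truth["pct_hypnotic"])
    assert prof.pct_any_psychotropic == pytest.approx(truth["pct_any_psychotropic"])
    assert prof.mortality_pct == pytest.approx(truth["mortality_pct"])
    assert prof.cmuc_pct_under60 == pytest.approx(truth["cmuc_pct_under60"])
    assert prof.comorbidity_pcts == pytest.approx(truth["comorbidity_pcts"])
    assert prof.cost_totals == pytest.approx(truth["cost_totals"])


def test_cost_grand_total_is_sum_of_components(fixture_bundle):
    prof = profile_cohort(fixture_bundle, fixture_bundle.beneficiary_ids)
    parts = (946, 624, 3697, 435, 581)
    assert tuple(prof.cost_totals[k] for k in ("ambulatory", "pharma", "hospital", "sick_leave", "disability")) == parts
    assert prof.cost_totals["total"] == sum(parts) == 6283


def test_single_member_cohort(fixture_bundle):
    prof = profile_cohort(fixture_bundle, {"b04"})  # 45-year-old man, alive
    assert prof.n == 1
    assert prof.pct_male == 100.0
    assert prof.mortality_pct == 0.0
    assert prof.age_mean == 45.0 and prof.age_sd == 0.0
    assert prof.age_iqr_low == prof.age_iqr_high == 45.0


def test_empty_cohort_profile(fixture_bundle):
    prof = profile_cohort(fixture_bundle, frozenset())
    assert prof.n == 0 and prof.age_mean is None and prof.mortality_pct is None
    assert prof.cost_totals["total"] == 0.0


def test_unknown_ids_rejected(fixture_bundle):
    with pytest.raises(ValueError):
        profile_cohort(fixture_bundle, {"nobody"})


def test_mortality_counts_study_year_deaths_only(fixture_bundle):
    # b08 dies in 2012, b09 dies in 2013: only the in-year death counts
    assert mortality_rate_pct(fixture_bundle, fixture_bundle.beneficiary_ids) == 10.0
    assert mortality_rate_pct(fixture_bundle, {"b09"}) == 0.0
    assert mortality_rate_pct(fixture_bundle, {"b08"}) == 100.0
    with pytest.raises(ValueError):
        mortality_rate_pct(fixture_bundle, frozenset())


def test_cmuc_rate_restricted_to_under_60(fixture_bundle):
    # under-60 members: b01, b02, b03, b04, b06, b10 — of whom b02, b03, b10 have CMUC
    assert cmuc_rate_under60_pct(fixture_bundle, fixture_bundle.beneficiary_ids) == 50.0
    # an all-60-plus cohort has no defined rate
    assert cmuc_rate_under60_pct(fixture_bundle, {"b05", "b08"}) is None
    assert cmuc_rate_under60_pct(fixture_bundle, {"b02", "b04"}) == 50.0


def test_profile_additive_over_disjoint_cohorts(small_bundle):
    ids = sorted(small_bundle.beneficiary_ids)
    left, right = frozenset(ids[:400]), frozenset(ids[400:])
    whole = profile_cohort(small_bundle, left | right)
    p_left = profile_cohort(small_bundle, left)
    p_right = profile_cohort(small_bundle, right)
    assert whole.n == p_left.n + p_right.n
    for key in whole.cost_totals:
        assert whole.cost_totals[key] == pytest.approx(
            p_left.cost_totals[key] + p_right.cost_totals[key]
        )


def test_generated_mortality_contrast_between_strata(medium_bundle):
    """The general-hospital associated-diagnosis stratum has markedly higher
    in-year mortality than the full-coverage population."""
    sel = run_selection(medium_bundle)
    m = sel.method_sets()
    d_only = sel.D_2y - m["A"] - m["B"] - m["C"]
    assert len(d_only) >= 20 and len(m["A"]) >= 20
    assert mortality_rate_pct(medium_bundle, d_only) > mortality_rate_pct(medium_bundle, m["A"])
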