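"""Selection rules: fixture truth, window boundaries, thresholds, properties."""

import dataclasses

import pandas as pd
import pytest

from depclaims import (
    antidepressant_users,
    bipolar_exclusion,
    empty_bundle,
    generate,
    calibrated_params,
    run_selection,
    select_method_b,
    select_method_d,
    tiny_fixture,
)
from depclaims.data_model import _canonical

from ._oracle import oracle_selection


def _with_rows(bundle, table, rows):
    """Bundle copy with extra rows appended to one table."""
    df = bundle.tables()[table]
    extra = pd.DataFrame(rows, columns=list(df.columns))
    merged = _canonical(pd.concat([df, extra], ignore_index=True), table)
    return dataclasses.replace(bundle, **{table: merged})


def test_fixture_selection_matches_hand_enumeration(fixture_bundle, fixture_truth):
    sel = run_selection(fixture_bundle)
    for label, expected in fixture_truth["sets"].items():
        if label == "excluded_bipolar":
            assert sorted(sel.excluded_bipolar) == expected
        else:
            assert sorted(getattr(sel, label)) == expected, label
    assert sel.denominator_count == fixture_truth["denominator_count"]
    assert sorted(antidepressant_users(fixture_bundle)) == fixture_truth["antidepressant_users"]


def test_antidepressant_threshold_counts_distinct_dates(fixture_bundle):
    users = antidepressant_users(fixture_bundle)
    assert "b01" in users          # 3 dispensings on 3 dates
    assert "b03" not in users      # only 2 dispensings
    assert "b04" not in users      # 4 dispensings but only 2 distinct dates


def test_method_a_requires_active_episode(fixture_bundle):
    sel = run_selection(fixture_bundle)
    assert "b01" in sel.A          # open-ended episode from 2010
    assert "b02" not in sel.A      # episode ended in 2011


def test_method_b_window_semantics(fixture_bundle):
    psy_1y, _ = select_method_b(fixture_bundle, 1)
    psy_2y, _ = select_method_b(fixture_bundle, 2)
    assert "b04" not in psy_1y and "b04" in psy_2y  # 2011 stay, study year 2012
    with pytest.raises(ValueError):
        select_method_b(fixture_bundle, 3)
    with pytest.raises(ValueError):
        select_method_d(fixture_bundle, 5)


def test_general_associated_dx_never_counts_for_method_b(fixture_bundle):
    # b08: general stay with depression only among associated diagnoses
    _, gen_principal = select_method_b(fixture_bundle, 2)
    assert "b08" not in gen_principal
    assert "b08" in select_method_d(fixture_bundle, 1)


def test_five_year_history_window_boundaries(fixture_bundle):
    sel = run_selection(fixture_bundle)
    assert "b05" in sel.C_psy_history      # stay in study_year - 4: inside
    assert "b06" not in sel.C_psy_history  # stay in study_year - 5: outside
    assert "b09" in sel.E                  # general associated stay in study_year - 4


def test_bipolar_exclusion_arms(fixture_bundle):
    excluded = bipolar_exclusion(fixture_bundle)
    assert excluded == frozenset({"b10"})  # F31 associated dx (2009) + lithium (2012)
    # without the exclusion b10 would have qualified for B via its 2012 stay
    psy_1y, _ = select_method_b(fixture_bundle, 1)
    assert "b10" in psy_1y
    assert "b10" not in run_selection(fixture_bundle).B_psy_1y


def test_bipolar_stay_outside_window_does_not_exclude():
    bundle = tiny_fixture()
    stays = bundle.hospital_stays
    # move b10's bipolar stay out of the 5-year window and drop its lithium
    stays.loc[stays["associated_dx"] == "F310", "admission_date"] = pd.Timestamp("2006-07-07")
    disp = bundle.dispensings
    bundle = dataclasses.replace(bundle, dispensings=disp[disp["atc"] != "N05AN01"].reset_index(drop=True))
    assert "b10" not in bipolar_exclusion(bundle)
    assert "b10" in run_selection(bundle).B_psy_1y


def test_empty_bundle_selects_nothing():
    sel = run_selection(empty_bundle(2012))
    assert all(s == frozenset() for s in sel.sets().values())
    assert sel.denominator_count == 0


def test_selection_result_invariants(small_bundle):
    sel = run_selection(small_bundle)
    ids = small_bundle.beneficiary_ids
    for label, s in sel.sets().items():
        assert s <= ids, label
        assert not (s & sel.excluded_bipolar), label  # exclusion dominance
    assert sel.B_psy_1y <= sel.B_psy_2y <= sel.psy_stay_history_5y
    assert sel.B_gen_principal_1y <= sel.B_gen_principal_2y <= sel.gen_principal_stay_history_5y
    assert sel.D_1y <= sel.D_2y
    assert sel.C_psy_history <= sel.psy_stay_history_5y
    assert sel.C_gen_principal_history <= sel.gen_principal_stay_history_5y


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_vectorised_selection_matches_per_individual_oracle(seed):
    bundle = generate(calibrated_params(1000, seed=seed))
    sel = run_selection(bundle)
    truth = oracle_selection(bundle)
    for label, expected in truth.items():
        got = sel.excluded_bipolar if label == "excluded_bipolar" else getattr(sel, label)
        assert got == expected, label


def test_adding_qualifying_record_is_monotone(fixture_bundle):
    before = run_selection(fixture_bundle)
    # a third distinct antidepressant date makes b03 a treatment user -> C
    grown = _with_rows(
        fixture_bundle, "dispensings", [("b03", "2012-09-09", "N06AB03")]
    )
    after = run_selection(grown)
    for label, s in before.sets().items():
        assert s <= after.sets()[label], label
    assert "b03" in after.C_psy_history and "b03" not in before.C_psy_history


def test_adding_bipolar_record_never_adds_members(fixture_bundle):
    before = run_selection(fixture_bundle)
    poisoned = _with_rows(
        fixture_bundle, "dispensings", [("b07", "2012-06-06", "N05AN01")]
    )
    after = run_selection(poisoned)
    for label, s in after.sets().items():
        assert s <= before.sets()[label], label
    assert "b07" in after.excluded_bipolar
    assert all("b07" not in s for s in after.sets().values())
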