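"""Incremental attribution, rounding, prevalence and overlap partitions."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from depclaims import (
    attribute_incremental,
    multi_source_rates,
    prevalence_pct,
    round_to_nearest_5,
    run_selection,
    venn_partition,
)
from depclaims.attribution import DEFAULT_ORDER

from ._oracle import oracle_venn


@pytest.mark.parametrize("n,expected", [(0, 0), (2, 0), (3, 5), (7, 5), (8, 10), (12, 10), (13, 15), (100, 100)])
def test_round_to_nearest_5(n, expected):
    assert round_to_nearest_5(n) == expected


def test_round_rejects_negative():
    with pytest.raises(ValueError):
        round_to_nearest_5(-1)


@given(n=st.integers(min_value=0, max_value=10**9))
def test_rounding_bound_and_multiple(n):
    r = round_to_nearest_5(n)
    assert r % 5 == 0 and abs(r - n) <= 2


@pytest.mark.parametrize(
    "count,denom,expected",
    [
        # national-scale figures: the published counts over the published denominator
        (544_105, 58_753_200, 0.93),
        (271_275, 58_753_200, 0.46),
        (969_300, 58_753_200, 1.65),
        (0, 100, 0.0),
        (1, 800, 0.13),   # 0.125 rounds half-up
    ],
)
def test_prevalence_pct(count, denom, expected):
    assert prevalence_pct(count, denom) == expected


def test_prevalence_input_validation():
    with pytest.raises(ValueError):
        prevalence_pct(1, 0)
    with pytest.raises(ValueError):
        prevalence_pct(5, 4)


def test_single_source_and_duplicate_source(fixture_bundle):
    sel = run_selection(fixture_bundle)
    res = attribute_incremental(sel, ["A"])
    assert len(res.rows) == 1 and res.rows[0].incremental_ids == sel.A
    with pytest.raises(ValueError):
        attribute_incremental(sel, ["A", "A"])
    with pytest.raises(KeyError):
        attribute_incremental(sel, ["A", "nonsense"])


def test_identical_sets_give_empty_second_increment(fixture_bundle):
    sel = run_selection(fixture_bundle)
    res = attribute_incremental(sel, ["B_gen_principal_1y", "B_gen_principal_2y"])
    # in the fixture both windows select exactly {b07}
    assert res.rows[1].incremental_count_raw == 0
    assert res.rows[1].cumulative_count_raw == 1


def test_default_order_attribution_on_fixture(fixture_bundle, fixture_truth):
    sel = run_selection(fixture_bundle)
    res = attribute_incremental(sel)
    assert [r.source_label for r in res.rows] == DEFAULT_ORDER
    union = frozenset().union(*sel.sets().values())
    assert res.rows[-1].cumulative_count_raw == len(union)
    # increments are disjoint and conserve the union
    seen = set()
    for row in res.rows:
        assert not (row.incremental_ids & seen)
        seen |= row.incremental_ids
    assert seen == union


def test_conservation_and_final_count_order_invariance(small_bundle):
    sel = run_selection(small_bundle)
    rng = random.Random(12)
    final_counts = set()
    for _ in range(30):
        order = DEFAULT_ORDER[:]
        rng.shuffle(order)
        res = attribute_incremental(sel, order)
        total_incremental = sum(r.incremental_count_raw for r in res.rows)
        assert total_incremental == res.rows[-1].cumulative_count_raw
        assert all(
            a.cumulative_count_raw <= b.cumulative_count_raw
            for a, b in zip(res.rows, res.rows[1:])
        )
        final_counts.add(res.rows[-1].cumulative_count_raw)
    assert len(final_counts) == 1


def test_venn_partition_trivial_cases():
    v = venn_partition({"x"}, {"y", "z"}, {"p", "q", "r"})
    assert (v.a_only, v.b_only, v.c_only) == (1, 2, 3)
    assert v.multi_source_count == 0 and v.multi_source_fraction == 0.0
    same = frozenset("wxyz")
    v2 = venn_partition(same, same, same)
    assert v2.abc == 4 and v2.multi_source_fraction == 1.0


@given(st.data())
def test_venn_partition_matches_membership_tally(data):
    universe = list(range(60))
    a = frozenset(data.draw(st.sets(st.sampled_from(universe))))
    b = frozenset(data.draw(st.sets(st.sampled_from(universe))))
    c = frozenset(data.draw(st.sets(st.sampled_from(universe))))
    v = venn_partition(a, b, c)
    tally = oracle_venn(a, b, c)
    assert v.a_only == tally["100"] and v.b_only == tally["010"] and v.c_only == tally["001"]
    assert v.ab_only == tally["110"] and v.ac_only == tally["101"] and v.bc_only == tally["011"]
    assert v.abc == tally["111"]
    assert v.union_size == len(a | b | c)


def test_multi_source_rates(small_bundle, fixture_bundle):
    sel = run_selection(small_bundle)
    rates = multi_source_rates(sel)
    m = sel.method_sets()
    for name in "ABC":
        others = frozenset().union(*(m[k] for k in "ABC" if k != name))
        expected = len(m[name] & others) / len(m[name]) if m[name] else None
        assert rates[name] == expected
    # nested case: every C member of the fixture is also in B
    fix = run_selection(fixture_bundle)
    fix_rates = multi_source_rates(fix)
    assert fix_rates["C"] == pytest.approx(0.5)  # b07 in B, b05 only in C
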