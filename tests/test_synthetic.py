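"""Generator: determinism, validity, and calibration of the latent structure."""

import dataclasses

import numpy as np
import pytest

from depclaims import (
    GeneratorParams,
    StayComponent,
    expected_multi_source_fraction,
    expected_selection_fractions,
    generate,
    calibrated_params,
    run_selection,
    validate_bundle,
)
from depclaims.data_model import bundle_equal
from depclaims.synthetic import (
    PUBLISHED_DENOMINATOR,
    PUBLISHED_MULTI_SOURCE_FRACTION,
    PUBLISHED_SUB_SOURCE_COUNTS,
)


def test_zero_population_gives_empty_bundle():
    bundle = generate(dataclasses.replace(calibrated_params(1), n=0))
    assert all(len(t) == 0 for t in bundle.tables().values())


def test_generation_is_deterministic_in_seed():
    p = calibrated_params(1000, seed=7)
    assert bundle_equal(generate(p), generate(p))
    different = generate(dataclasses.replace(p, seed=8))
    assert not bundle_equal(generate(p), different)


def test_generated_bundles_are_valid(small_bundle):
    assert validate_bundle(small_bundle) == []


def test_all_mass_on_none_selects_nobody():
    empty_comp = StayComponent(0.0, 0.0, 0.0)
    params = GeneratorParams(
        n=500,
        psy=empty_comp,
        gen_principal=empty_comp,
        gen_associated=empty_comp,
        p_ald_given_structure=0.0,
        p_ald_baseline=0.0,
        treat_recent=0.0,
        treat_history=0.0,
        p_bipolar=0.0,
        seed=3,
        p_expired_dep_ald=0.0,
    )
    sel = run_selection(generate(params))
    assert all(s == frozenset() for s in sel.sets().values())
    assert sel.excluded_bipolar == frozenset()


def test_invalid_params_rejected():
    comp = StayComponent(0.6, 0.5, 0.2)  # sums beyond 1
    with pytest.raises(ValueError):
        GeneratorParams(
            n=10, psy=comp, gen_principal=comp, gen_associated=comp,
            p_ald_given_structure=0.1, p_ald_baseline=0.01,
            treat_recent=0.5, treat_history=0.5,
        ).validate()
    with pytest.raises(ValueError):
        calibrated_params(0)


def test_calibrated_expectations_match_published_fractions():
    """The analytic expectation of every sub-source fraction equals the
    published count over the published denominator (the small residual comes
    from rare cross-source joint memberships the calibration neglects)."""
    params = calibrated_params(100_000)
    expected = expected_selection_fractions(params)
    for label, count in PUBLISHED_SUB_SOURCE_COUNTS.items():
        target = count / PUBLISHED_DENOMINATOR
        assert expected[label] == pytest.approx(target, rel=0.01), label
    assert expected_multi_source_fraction(params) == pytest.approx(
        PUBLISHED_MULTI_SOURCE_FRACTION, abs=1e-6
    )


def test_realised_fractions_track_expectations_at_moderate_n(medium_bundle):
    """Monte-Carlo check: realised sub-source fractions at n=20,000 stay
    within 4 binomial standard errors of their generating expectations."""
    n = len(medium_bundle.beneficiaries)
    params = calibrated_params(n, seed=4)
    expected = expected_selection_fractions(params)
    sel = run_selection(medium_bundle)
    for label, s in sel.sets().items():
        mean = n * expected[label]
        se = np.sqrt(mean * (1 - expected[label]))
        assert abs(len(s) - mean) <= 4 * se, (label, len(s), mean)


def test_excluded_fraction_tracks_bipolar_rate(medium_bundle):
    n = len(medium_bundle.beneficiaries)
    p_bip = calibrated_params(n, seed=4).p_bipolar
    excluded = run_selection(medium_bundle).excluded_bipolar
    se = np.sqrt(n * p_bip * (1 - p_bip))
    assert abs(len(excluded) - n * p_bip) <= 4 * se


def test_bipolar_contamination_is_exercised():
    """Bipolar persons draw depression-like records independently, so with a
    dense parameterisation some would qualify for a method were they not
    excluded — the exclusion rule must have real work to do."""
    comp = StayComponent(0.25, 0.15, 0.15)
    params = GeneratorParams(
        n=400, seed=9,
        psy=comp, gen_principal=comp, gen_associated=comp,
        p_ald_given_structure=0.3, p_ald_baseline=0.05,
        treat_recent=0.5, treat_history=0.8,
        p_bipolar=0.3,
    )
    bundle = generate(params)
    sel = run_selection(bundle)
    from depclaims import select_method_b, select_method_d

    raw_union = (
        frozenset().union(*select_method_b(bundle, 2))
        | select_method_d(bundle, 2)
    )
    assert sel.excluded_bipolar & raw_union
    assert not sel.excluded_bipolar & frozenset().union(*sel.sets().values())
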