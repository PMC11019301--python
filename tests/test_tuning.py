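"""Lambda_max estimation against the reference panel."""

import itertools

import pytest

from uvopsin.numbering import AMBIGUOUS, TUNING_SITES
from uvopsin.tuning import (
    ReferenceEntry,
    SiteEffect,
    TuningError,
    classify_variant,
    estimate_lambda_max,
    load_reference_panel,
    match_reference,
    polarity_change,
)


@pytest.mark.parametrize(
    "site,a,b,expected",
    [
        (125, "S", "A", True),   # the putative tuning site's polarity shift
        (114, "S", "T", False),  # both polar
        (118, "A", "G", False),  # both nonpolar
        (113, "E", "K", False),  # both charged, hence polar
        (90, "S", "F", True),
    ],
)
def test_polarity_change(site, a, b, expected):
    assert polarity_change(site, a, b) is expected


def test_polarity_undefined_for_sentinels():
    assert polarity_change(114, "X", "A") is None
    assert polarity_change(114, "-", "A") is None


def _mini_panel(short_profile, long_profile):
    return [
        ReferenceEntry("Fish_a", "SWS1", dict(short_profile), 360.0, "MSP", False),
        ReferenceEntry("Damsel_b", "SWS1", dict(long_profile), 368.0, "MSP", True),
        ReferenceEntry("Fish_c", "SWS1", {**short_profile, 116: "A"}, 358.0, "in-vitro", False),
    ]


def test_match_identity_ranks_first(short_profile, long_profile):
    ranked = match_reference(short_profile, _mini_panel(short_profile, long_profile))
    entry, mismatches = ranked[0]
    assert entry.species == "Fish_a" and mismatches == []


def test_match_single_substitution(short_profile, long_profile):
    query = {**short_profile, 265: "Y"}
    ranked = match_reference(query, _mini_panel(short_profile, long_profile))
    entry, mismatches = ranked[0]
    assert entry.species == "Fish_a" and mismatches == [265]


def test_damselfish_preferred_on_ties(short_profile, long_profile):
    # query equidistant (1 mismatch) from a damselfish and a non-damselfish entry
    panel = [
        ReferenceEntry("Aaa_nondamsel", "SWS1", dict(short_profile), 360.0, "in-vitro", False),
        ReferenceEntry("Zzz_damsel", "SWS1", dict(short_profile), 360.0, "MSP", True),
    ]
    query = {**short_profile, 46: "Y"}
    ranked = match_reference(query, panel)
    assert ranked[0][0].species == "Zzz_damsel"


def test_all_missing_profile_matches_nothing(short_profile, long_profile):
    ranked = match_reference({s: "-" for s in TUNING_SITES}, _mini_panel(short_profile, long_profile))
    assert ranked == []


def test_estimate_identity_needs_no_effects(short_profile, long_profile, effects):
    est = estimate_lambda_max(short_profile, _mini_panel(short_profile, long_profile), effects)
    assert est.lambda_max_nm == 360.0 and est.applied_effects == ()


def test_a118s_shift_applied(short_profile, effects):
    panel = [ReferenceEntry("Ref", "SWS1", dict(short_profile), 360.0, "MSP", True)]
    est = estimate_lambda_max({**short_profile, 118: "S"}, panel, effects)
    assert est.lambda_max_nm == 365.0
    assert [e.delta_nm for e in est.applied_effects] == [5.0]


def test_joint_substitution_sums_both_effects(short_profile, effects):
    ss = {**short_profile, 114: "S", 118: "S"}
    panel = [ReferenceEntry("Ref", "SWS1", ss, 370.0, "MSP", True)]
    est = estimate_lambda_max(short_profile, panel, effects)
    assert est.lambda_max_nm == 360.0  # -5 (S114A) and -5 (S118A)
    assert est.variant_class == "short"


def test_ambiguous_site_is_undetermined(short_profile, panel, effects):
    est = estimate_lambda_max({**short_profile, 114: AMBIGUOUS}, panel, effects)
    assert not est.determined and "ambiguous" in est.reason


def test_unknown_substitution_refused_at_default_threshold(short_profile, effects):
    panel = [ReferenceEntry("Ref", "SWS1", dict(short_profile), 360.0, "MSP", True)]
    query = {**short_profile, 265: "Y"}  # no packaged effect at 265
    est = estimate_lambda_max(query, panel, effects)
    assert not est.determined and est.n_unmatched_sites == 1
    # relaxing the homology threshold admits the estimate without the shift
    est = estimate_lambda_max(query, panel, effects, homology_threshold=1)
    assert est.lambda_max_nm == 360.0


def test_direction_symmetry(short_profile, effects):
    """Estimating A->B then B->A over the same site returns shifts summing to 0."""
    ss = {**short_profile, 118: "S"}
    panel_a = [ReferenceEntry("Ref", "SWS1", dict(short_profile), 360.0, "MSP", True)]
    panel_b = [ReferenceEntry("Ref", "SWS1", ss, 365.0, "MSP", True)]
    fwd = estimate_lambda_max(ss, panel_a, effects)
    back = estimate_lambda_max(short_profile, panel_b, effects)
    delta_fwd = fwd.lambda_max_nm - 360.0
    delta_back = back.lambda_max_nm - 365.0
    assert delta_fwd + delta_back == 0.0


def test_panel_order_never_changes_estimate(short_profile, long_profile, effects):
    panel = _mini_panel(short_profile, long_profile)
    query = {**short_profile, 118: "S"}
    values = {
        estimate_lambda_max(query, list(perm), effects).lambda_max_nm
        for perm in itertools.permutations(panel)
    }
    assert len(values) == 1


def test_class_dichotomy_on_packaged_panel(panel, effects, short_profile):
    """AA profiles land in the short class and SS profiles in the long class
    from any damselfish starting reference in the packaged panel."""
    for entry in panel:
        if not entry.is_damselfish:
            continue
        aa = {**{s: entry.profile[s] for s in TUNING_SITES}, 114: "A", 118: "A"}
        ss = {**{s: entry.profile[s] for s in TUNING_SITES}, 114: "S", 118: "S"}
        est_aa = estimate_lambda_max(aa, panel, effects)
        est_ss = estimate_lambda_max(ss, panel, effects)
        assert 356.0 <= est_aa.lambda_max_nm <= 362.0
        assert 368.0 <= est_ss.lambda_max_nm <= 370.0


@pytest.mark.parametrize(
    "value,label",
    [
        (356.0, "short"), (360.0, "short"), (362.0, "short"),
        (368.0, "long"), (370.0, "long"),
        (365.0, "intermediate"), (362.5, "intermediate"),
        (350.0, "unclassified"), (375.0, "unclassified"), (None, "unclassified"),
    ],
)
def test_classify_variant_bins(value, label):
    assert classify_variant(value) == label


def test_reference_lambda_range_enforced(short_profile):
    with pytest.raises(TuningError, match="plausible SWS1"):
        ReferenceEntry("Bad", "SWS1", dict(short_profile), 500.0, "MSP", False)


def test_packaged_panel_loads(panel):
    assert any(e.is_damselfish for e in panel)
    assert all(330 <= e.lambda_max_nm <= 420 for e in panel)
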