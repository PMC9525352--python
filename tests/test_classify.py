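"""Specificity classification and most-sensitive-endpoint determination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dntbattery import (
    BMCEstimate,
    CompoundProfile,
    ci_overlap_fraction,
    classify_npc,
    classify_ukn,
    most_sensitive_endpoint,
)
from dntbattery.errors import ConfigurationError


def est(bmc=None, ci=None, endpoint="E", compound="A", bmr=20.0):
    if bmc is None:
        return BMCEstimate(bmr, "decrease", compound_id=compound, endpoint_id=endpoint)
    lo, hi = ci if ci else (bmc, bmc)
    return BMCEstimate(
        bmr, "decrease", bmc=bmc, censored=False, ci_lower=lo, ci_upper=hi,
        compound_id=compound, endpoint_id=endpoint,
    )


class TestCIOverlapFraction:
    @pytest.mark.parametrize(
        "dnt, ref, expected",
        [
            ((1, 2), (3, 4), 0.0),  # disjoint
            ((1, 2), (1, 2), 1.0),  # identity
            ((1, 2), (1.95, 3), 0.05),  # 5% of the DNT interval
            ((1, 2), (1.5, 2.5), 0.5),
        ],
    )
    def test_interval_arithmetic(self, dnt, ref, expected):
        assert ci_overlap_fraction(dnt, ref) == pytest.approx(expected)

    def test_degenerate_dnt_interval_measured_against_reference(self):
        assert ci_overlap_fraction((1.5, 1.5), (1.0, 2.0)) == pytest.approx(0.0)
        # the reference interval provides the denominator once the DNT
        # interval has zero length; intersection is still length zero
        assert ci_overlap_fraction((1.0, 3.0), (2.0, 2.0)) == 0.0

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            ci_overlap_fraction((2, 1), (0, 1))

    @given(
        a=st.floats(0.01, 10), w1=st.floats(0.01, 5),
        b=st.floats(0.01, 10), w2=st.floats(0.01, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_fraction_bounded_and_direct_arithmetic(self, a, w1, b, w2):
        dnt, ref = (a, a + w1), (b, b + w2)
        frac = ci_overlap_fraction(dnt, ref)
        inter = max(0.0, min(dnt[1], ref[1]) - max(dnt[0], ref[0]))
        assert 0.0 <= frac <= 1.0
        assert frac == pytest.approx(min(1.0, inter / w1))


class TestClassifyNPC:
    def test_censored_dnt_is_no_hit(self):
        call = classify_npc(est(None), [est(1.0, (0.5, 1.5))])
        assert call.classification == "no_hit"

    def test_all_references_censored_is_specific(self):
        call = classify_npc(est(0.7, (0.5, 1.0)), [est(None, endpoint="LDH")])
        assert call.classification == "specific"
        assert call.overlap_fraction == 0.0

    def test_small_overlap_is_borderline(self):
        call = classify_npc(est(1.5, (1, 2)), [est(2.2, (1.95, 3), endpoint="LDH")])
        assert call.classification == "borderline"
        assert call.overlap_fraction == pytest.approx(0.05)
        assert call.reference_endpoint_used == "LDH"

    def test_ten_percent_overlap_is_unspecific_inclusive(self):
        call = classify_npc(est(1.5, (1, 2)), [est(2.4, (1.9, 3))])
        assert call.overlap_fraction == pytest.approx(0.10)
        assert call.classification == "unspecific"

    def test_half_overlap_is_unspecific(self):
        call = classify_npc(est(1.5, (1, 2)), [est(2.0, (1.5, 2.5))])
        assert call.classification == "unspecific"

    def test_worst_reference_wins_regardless_of_order(self):
        refs = [est(5.0, (4, 6), endpoint="CTB"), est(2.0, (1.5, 2.5), endpoint="LDH")]
        a = classify_npc(est(1.5, (1, 2)), refs)
        b = classify_npc(est(1.5, (1, 2)), refs[::-1])
        assert a.classification == b.classification == "unspecific"
        assert a.reference_endpoint_used == b.reference_endpoint_used == "LDH"

    def test_degenerate_cis_fall_back_to_bmc_ratio(self):
        # noise-free bootstrap collapses every CI to a point
        dnt = est(0.4, (0.4, 0.4))
        assert classify_npc(dnt, [est(0.7, (0.7, 0.7))]).classification == "borderline"
        assert classify_npc(dnt, [est(0.4, (0.4, 0.4))]).classification == "unspecific"
        far = classify_npc(dnt, [est(4.0, (4.0, 4.0))])
        assert far.classification == "specific"
        assert far.basis == "viability_ratio"
        assert far.ratio_value == pytest.approx(10.0)

    def test_empty_reference_list_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            classify_npc(est(1.0, (0.5, 1.5)), [])


class TestClassifyUKN:
    def test_ratio_cutoff_inclusive_for_ukn2(self):
        call = classify_ukn("ukn2", est(5.0, bmr=25), est(6.5, bmr=10))
        assert call.classification == "specific"
        assert call.ratio_value == pytest.approx(1.3)

    def test_ukn4_ratio_below_cutoff_is_unspecific(self):
        call = classify_ukn("ukn4", est(5.0, bmr=25), est(10.0, bmr=25))
        assert call.classification == "unspecific"
        assert call.ratio_value == pytest.approx(2.0)

    def test_viability_censored_is_specific(self):
        call = classify_ukn("ukn5", est(2.0, bmr=25), est(None, bmr=25))
        assert call.classification == "specific"
        assert np.isinf(call.ratio_value)

    def test_censored_endpoint_is_no_hit(self):
        assert classify_ukn("ukn2", est(None), est(1.0)).classification == "no_hit"

    def test_unknown_assay_rejected(self):
        with pytest.raises(ConfigurationError):
            classify_ukn("ukn9", est(1.0), est(2.0))


def profile_with(calls):
    prof = CompoundProfile("A")
    for ep, (bmc, cls) in calls.items():
        prof.bmcs[ep] = est(bmc, endpoint=ep)
        prof.hit_calls[ep] = classify_npc(
            est(bmc, (bmc * 0.9, bmc * 1.1), endpoint=ep), [est(None)]
        ) if cls == "specific" else None
        # build the call directly to control the classification
        from dntbattery.classify import HitCall

        prof.hit_calls[ep] = HitCall("A", ep, cls, "ci_overlap", overlap_fraction=0.0)
    return prof


class TestMostSensitiveEndpoint:
    def test_minimum_specific_bmc_wins(self):
        prof = profile_with({"NPC5": (0.5, "specific"), "UKN2": (2.0, "specific")})
        assert most_sensitive_endpoint(prof) == ("NPC5", 0.5)

    def test_no_specific_hits_returns_none(self):
        prof = profile_with({"NPC5": (0.5, "unspecific"), "UKN2": (2.0, "no_hit")})
        assert most_sensitive_endpoint(prof) is None
        assert prof.mse_endpoint is None and prof.mse_bmc is None

    def test_unspecific_bmcs_never_win(self):
        prof = profile_with({"A_ep": (1.0, "specific"), "B_ep": (0.1, "unspecific")})
        assert most_sensitive_endpoint(prof) == ("A_ep", 1.0)

    def test_ties_break_lexicographically(self):
        prof = profile_with({"NPC5": (0.5, "specific"), "NPC1": (0.5, "specific")})
        assert most_sensitive_endpoint(prof) == ("NPC1", 0.5)
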