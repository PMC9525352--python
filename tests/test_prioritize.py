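"""ToxPi slice scaling, clustering, and the merged MSE + ToxPi ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dntbattery import (
    cluster_profiles,
    fold_range_tie_groups,
    merged_rank,
    rank_by_mse,
    rank_by_toxpi,
    scale_bmcs,
    toxpi_scores,
)
from dntbattery.errors import ConfigurationError


def matrix(data, endpoints=None):
    return pd.DataFrame(data).T if endpoints is None else pd.DataFrame(data, columns=endpoints)


class TestScaleBMCs:
    def test_censored_entry_scales_to_exactly_zero(self):
        m = pd.DataFrame({"E": [np.nan, 1.0]}, index=["A", "B"])
        raw, scaled = scale_bmcs(m)
        assert raw.loc["A", "E"] == 0.0
        assert scaled.loc["A", "E"] == 0.0

    def test_per_endpoint_max_normalization(self):
        m = pd.DataFrame({"E": [1.0, 10.0]}, index=["A", "B"])
        raw, scaled = scale_bmcs(m)
        np.testing.assert_allclose(raw["E"], [6.0, 5.0])
        np.testing.assert_allclose(scaled["E"], [1.0, 5.0 / 6.0])

    def test_single_compound_endpoint_scales_to_one(self):
        _, scaled = scale_bmcs(pd.DataFrame({"E": [20.0]}, index=["A"]))
        assert scaled.loc["A", "E"] == 1.0

    def test_fully_censored_endpoint_stays_zero(self):
        _, scaled = scale_bmcs(pd.DataFrame({"E": [np.nan, np.nan]}, index=["A", "B"]))
        assert (scaled["E"] == 0.0).all()

    def test_global_strategy_uses_one_denominator(self):
        m = pd.DataFrame({"E1": [0.01, 1.0], "E2": [1.0, 10.0]}, index=["A", "B"])
        _, scaled = scale_bmcs(m, strategy="global")
        assert scaled.loc["A", "E1"] == 1.0
        assert scaled.loc["B", "E2"] < scaled.loc["A", "E2"] < 1.0

    def test_nonpositive_bmc_rejected(self):
        with pytest.raises(ValueError):
            scale_bmcs(pd.DataFrame({"E": [-1.0]}, index=["A"]))

    @given(bmc=st.floats(1e-4, 1e4), lower=st.floats(0.1, 0.9))
    @settings(max_examples=50, deadline=None)
    def test_lower_bmc_never_lowers_slice_score(self, bmc, lower):
        m = pd.DataFrame({"E": [bmc, 5.0]}, index=["A", "B"])
        m2 = pd.DataFrame({"E": [bmc * lower, 5.0]}, index=["A", "B"])
        _, s1 = scale_bmcs(m)
        _, s2 = scale_bmcs(m2)
        assert s2.loc["A", "E"] >= s1.loc["A", "E"] - 1e-12


class TestToxPiScores:
    def test_all_zero_slices_score_zero(self):
        scaled = pd.DataFrame(0.0, index=["A"], columns=list("WXYZ"))
        assert toxpi_scores(scaled)["A"] == 0.0

    def test_equal_weight_mean(self):
        scaled = pd.DataFrame([[1.0, 0.0, 0.0, 0.0]], index=["A"], columns=list("WXYZ"))
        assert toxpi_scores(scaled)["A"] == pytest.approx(0.25)

    def test_upweighting_a_maximal_slice_increases_score(self):
        scaled = pd.DataFrame([[1.0, 0.2, 0.2, 0.2]], index=["A"], columns=list("WXYZ"))
        base = toxpi_scores(scaled)["A"]
        up = toxpi_scores(scaled, {"W": 2.0, "X": 1.0, "Y": 1.0, "Z": 1.0})["A"]
        assert up > base

    def test_unknown_endpoint_in_weights_rejected(self):
        scaled = pd.DataFrame([[1.0]], index=["A"], columns=["E"])
        with pytest.raises(ConfigurationError):
            toxpi_scores(scaled, {"nope": 1.0})


class TestClusterProfiles:
    def test_identical_profiles_merge_at_distance_zero(self):
        scaled = pd.DataFrame([[1, 0], [1, 0]], index=["A", "B"], columns=["E1", "E2"], dtype=float)
        res = cluster_profiles(scaled)
        assert res.linkage_matrix[0, 2] == 0.0

    def test_identical_pair_merges_before_orthogonal_profile(self):
        scaled = pd.DataFrame(
            [[1, 0], [1, 0], [0, 1]], index=["A", "B", "C"], columns=["E1", "E2"], dtype=float
        )
        res = cluster_profiles(scaled)
        assert res.cut(2)["A"] == res.cut(2)["B"] != res.cut(2)["C"]

    def test_input_order_does_not_change_partition(self):
        rng = np.random.default_rng(3)
        scaled = pd.DataFrame(
            rng.uniform(size=(6, 4)), index=list("ABCDEF"), columns=list("WXYZ")
        )
        base = cluster_profiles(scaled).cut(3)
        for perm in itertools.islice(itertools.permutations(scaled.index), 5):
            shuffled = cluster_profiles(scaled.loc[list(perm)]).cut(3)
            # same partition of compounds, up to cluster relabelling
            groups = lambda cut: {frozenset(k for k, v in cut.items() if v == c) for c in set(cut.values())}
            assert groups(shuffled) == groups(base)

    def test_single_compound_is_trivial(self):
        res = cluster_profiles(pd.DataFrame([[1.0]], index=["A"], columns=["E"]))
        assert res.labels == ["A"] and len(res.linkage_matrix) == 0


def brute_force_groups(bmcs, fold=3.0):
    """Independent transitive closure on 3-fold ranges via repeated merging."""
    groups = [{c} for c in bmcs]
    merged = True
    while merged:
        merged = False
        for i, j in itertools.combinations(range(len(groups)), 2):
            if any(
                min(bmcs[a] * fold, bmcs[b] * fold) >= max(bmcs[a] / fold, bmcs[b] / fold)
                for a in groups[i]
                for b in groups[j]
            ):
                groups[i] |= groups.pop(j)
                merged = True
                break
    return sorted([sorted(g) for g in groups], key=lambda g: min(bmcs[c] for c in g))


class TestMergedRank:
    def test_overlapping_fold_ranges_resolved_by_toxpi(self):
        order = merged_rank({"A": 0.02, "B": 0.12}, {"A": 0.1, "B": 0.9}).order
        assert order == ["B", "A"]  # one tie group; ToxPi decides

    def test_disjoint_ranges_follow_mse_regardless_of_toxpi(self):
        res = merged_rank({"A": 0.02, "C": 0.86}, {"A": 0.1, "C": 0.9})
        assert res.order == ["A", "C"]
        assert res.tie_groups == [["A"], ["C"]]

    def test_no_specific_hits_anywhere_falls_back_to_toxpi_order(self):
        res = merged_rank({"A": None, "B": None}, {"A": 0.2, "B": 0.7})
        assert res.order == rank_by_toxpi({"A": 0.2, "B": 0.7}).order == ["B", "A"]

    def test_compounds_without_mse_rank_last(self):
        res = merged_rank({"A": 5.0, "B": None}, {"A": 0.0, "B": 1.0})
        assert res.order == ["A", "B"]

    def test_ordering_is_a_stable_permutation(self):
        mse = {"A": 0.02, "B": 0.12, "C": 0.86, "D": None}
        toxpi = {"A": 0.3, "B": 0.8, "C": 0.1, "D": 0.5}
        r1, r2 = merged_rank(mse, toxpi), merged_rank(mse, toxpi)
        assert r1.order == r2.order
        assert sorted(r1.order) == sorted(mse)

    @given(
        bmcs=st.lists(st.floats(1e-3, 1e3), min_size=1, max_size=8).map(
            lambda xs: {f"C{i}": x for i, x in enumerate(xs)}
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_tie_groups_equal_brute_force_closure(self, bmcs):
        got = [sorted(g) for g in fold_range_tie_groups(bmcs)]
        assert got == brute_force_groups(bmcs)


class TestMSERanking:
    def test_ascending_bmc_order(self):
        res = rank_by_mse({"X": 2.0, "Y": 0.5, "Z": 1.0})
        assert res.order == ["Y", "Z", "X"]
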