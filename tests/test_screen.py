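"""Binder selection: Z-scores, percentile ranks, trough cutoff, overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rbpscreen import (ScreenConfig, find_trough_cutoff, median_rank_profile,
                       overlap_analysis, percentile_rank, select_binders,
                       zscore_select)
from rbpscreen.screen import (DegenerateArrayError, InsufficientDataError,
                              NoTroughError, RankProfile)


class TestPercentileRank:
    def test_no_ties(self):
        assert percentile_rank([10, 20, 30]).tolist() == \
            pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_ties_share_average_rank(self):
        assert percentile_rank([5, 5, 10]).tolist() == \
            pytest.approx([0.5, 0.5, 1.0])

    def test_missing_values_stay_missing(self):
        r = percentile_rank([1.0, np.nan, 2.0])
        assert np.isnan(r[1])
        assert r[[0, 2]].tolist() == pytest.approx([0.5, 1.0])

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            percentile_rank([1.0, np.nan])

    @settings(deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=40, unique=True))
    def test_invariant_under_monotone_transform(self, xs):
        # doubling is exact and strictly increasing: order preserved bitwise
        x = np.array(xs)
        np.testing.assert_allclose(percentile_rank(x), percentile_rank(2 * x))

    def test_invariant_under_exponential_transform(self, rng):
        x = rng.normal(0, 3, size=30)
        np.testing.assert_allclose(percentile_rank(x), percentile_rank(np.exp(x)))


class TestZscoreSelect:
    def test_textbook_example_not_selected(self):
        # {1,1,1,1,11}: sample SD 4.472, Z(11) about 2.236 under median center
        table = pd.DataFrame({"a1": [1.0, 1, 1, 1, 11]},
                             index=list("ABCDE"))
        sel = zscore_select(table, ScreenConfig())
        assert sel.score["E"] == pytest.approx(10 / np.sqrt(20), abs=1e-9)
        assert sel.selected == set()

    def test_degenerate_array_raises(self):
        table = pd.DataFrame({"a1": [2.0, 2.0, 2.0, 2.0]})
        with pytest.raises(DegenerateArrayError, match="a1"):
            zscore_select(table)

    def test_strong_feature_selected_in_all_replicates(self, rng):
        data = rng.normal(0, 1, size=(100, 2))
        data[0] = [30.0, 28.0]
        table = pd.DataFrame(data, index=[f"F{i}" for i in range(100)],
                             columns=["r1", "r2"])
        sel = zscore_select(table)
        assert "F0" in sel.selected
        assert sel.score["F0"] == sel.score.max()

    def test_mean_center_mode(self):
        table = pd.DataFrame({"a1": [0.0, 0, 0, 0, 10]}, index=list("ABCDE"))
        sel_med = zscore_select(table, ScreenConfig(center="median"))
        sel_mean = zscore_select(table, ScreenConfig(center="mean"))
        assert sel_mean.score["E"] < sel_med.score["E"]

    def test_affine_invariance(self, rng):
        data = rng.normal(5, 2, size=(50, 3))
        table = pd.DataFrame(data, index=[f"F{i}" for i in range(50)],
                             columns=list("abc"))
        transformed = table * np.array([2.0, 0.5, 7.0]) + \
            np.array([10.0, -3.0, 0.1])
        s1 = zscore_select(table)
        s2 = zscore_select(transformed)
        pd.testing.assert_series_equal(s1.score, s2.score, atol=1e-9)


class TestMedianRankProfile:
    def test_median_of_five(self):
        ranks = [0.95, 0.91, 0.99, 0.20, 0.97]
        # build a 1-feature-of-interest table realizing these ranks
        n = 100
        table = pd.DataFrame(
            {f"a{j}": np.arange(1.0, n + 1) for j in range(5)},
            index=[f"F{i}" for i in range(n)])
        # move feature F0 to the value achieving the desired rank per array
        for j, r in enumerate(ranks):
            col = f"a{j}"
            table.loc["F0", col] = r * n + 0.5  # lands between integers
        prof = median_rank_profile(table)
        assert prof.median_rank["F0"] == pytest.approx(0.95, abs=0.01)

    def test_low_presence_feature_excluded(self):
        table = pd.DataFrame(np.arange(50, dtype=float).reshape(10, 5),
                             index=[f"F{i}" for i in range(10)],
                             columns=[f"a{j}" for j in range(5)])
        table.loc["F0", ["a0", "a1", "a2"]] = np.nan  # data in 2/5 arrays
        prof = median_rank_profile(table, ScreenConfig(min_presence=0.5))
        assert "F0" in prof.excluded
        assert "F0" not in prof.median_rank.index

    def test_even_count_median_is_mean_of_middle(self):
        table = pd.DataFrame({"a1": np.arange(1.0, 11),
                              "a2": np.arange(10.0, 0, -1)},
                             index=[f"F{i}" for i in range(10)])
        prof = median_rank_profile(table)
        # every feature has ranks r and 1.1-r; median = mean of the two
        f3 = prof.median_rank["F3"]
        assert f3 == pytest.approx((0.4 + 0.7) / 2)


class TestFindTroughCutoff:
    def test_empty_gap_forces_valley(self, rng):
        mr = np.concatenate([rng.uniform(0, 0.85, 3800),
                             rng.uniform(0.92, 1.0, 200)])
        cutoff = find_trough_cutoff(mr)
        assert 0.85 <= cutoff <= 0.92

    def test_override_bypasses_detection(self):
        cfg = ScreenConfig(cutoff_override=0.9)
        assert find_trough_cutoff([0.5] * 200, cfg) == 0.9

    def test_unimodal_raises(self, rng):
        mr = rng.uniform(0.5, 1.0, 4000)  # flat: only shallow noise dips
        with pytest.raises(NoTroughError, match="cutoff_override"):
            find_trough_cutoff(mr)

    def test_too_few_values_requires_override(self):
        with pytest.raises(InsufficientDataError):
            find_trough_cutoff([0.5, 0.9] * 10)

    def test_bimodal_beta_mixture_recovered(self, rng):
        # background median ranks cluster near 0.5, binders near 0.97
        mr = np.concatenate([rng.beta(3, 3, 5000),
                             rng.uniform(0.94, 1.0, 300)])
        cutoff = find_trough_cutoff(mr)
        assert 0.80 <= cutoff <= 0.94


class TestSelectBinders:
    @pytest.fixture
    def profile(self):
        med = pd.Series({"A": 0.96, "B": 0.91, "C": 0.50})
        return RankProfile(ranks=pd.DataFrame(), median_rank=med, excluded=[])

    def test_cutoff_095(self, profile):
        assert select_binders(profile, 0.95).selected == {"A"}

    def test_cutoff_090(self, profile):
        assert select_binders(profile, 0.90).selected == {"A", "B"}

    def test_empty_selection_is_valid(self, profile):
        assert select_binders(profile, 0.999).selected == set()

    def test_selection_is_strictly_greater(self, profile):
        assert select_binders(profile, 0.96).selected == set()


class TestOverlapAnalysis:
    def test_published_set_sizes(self):
        a = {f"t{i}" for i in range(67)}            # total-RNA binders
        b = {f"t{i}" for i in range(7, 180)}        # mRNA binders, union 180
        out = overlap_analysis(a, b)
        assert out["n_intersection"] == 60
        assert out["n_union"] == 180
        assert out["pct_a_in_b"] == 90
        assert out["n_b_only"] == 113
        assert out["pct_b_only"] == 65

    def test_disjoint_sets(self):
        out = overlap_analysis({"x"}, {"y"})
        assert out["n_intersection"] == 0 and out["n_union"] == 2
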