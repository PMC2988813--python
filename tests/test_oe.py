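"""Overexpression profiling: QC, per-gene stats, shift and Fisher tests."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rbpscreen import (OeConfig, OeDataset, changed_genes, gene_stats,
                       gen_overexpression, oe_qc_filter, overrep_fisher,
                       target_shift)


def fisher_two_sided_by_enumeration(table):
    """Oracle: sum of probabilities of all tables with mass <= observed.

    Exact rational arithmetic, so the tie comparison has no float slack.
    """
    from fractions import Fraction

    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2

    def prob(x):  # x = top-left cell
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(N, c1))

    p_obs = prob(a)
    return float(sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
                     if prob(x) <= p_obs))


def _oe_dataset(ratios, sob=None, regcorr=None, reps=3):
    idx = [f"G{i}" for i in range(len(ratios))]
    cols = [f"rep{j+1}" for j in range(reps)]
    log2 = pd.DataFrame(ratios, index=idx, columns=cols)
    sob_d = None
    if sob is not None:
        sob_d = {ch: pd.DataFrame(m, index=idx, columns=cols)
                 for ch, m in sob.items()}
    rc = None if regcorr is None else pd.DataFrame(regcorr, index=idx,
                                                   columns=cols)
    return OeDataset(log2, sob_d, rc)


class TestOeQcFilter:
    def test_good_spot_retained(self):
        ds = _oe_dataset([[0.5, 0.5, 0.5]],
                         sob={"Cy3": [[2.5] * 3], "Cy5": [[2.5] * 3]},
                         regcorr=[[0.8] * 3])
        out, report = oe_qc_filter(ds)
        assert report["n_masked"] == 0
        assert out.log2_ratio.notna().all().all()

    def test_low_sob_one_channel_masks_spot(self):
        sob5 = [[2.5, 2.5, 2.5]]
        sob3 = [[1.9, 2.5, 2.5]]  # below 2.0 in one channel
        ds = _oe_dataset([[0.5] * 3], sob={"Cy3": sob3, "Cy5": sob5})
        out, report = oe_qc_filter(ds)
        assert np.isnan(out.log2_ratio.iloc[0, 0])
        assert report["n_masked"] == 1

    def test_regcorr_direction_policies(self):
        ds = _oe_dataset([[0.5] * 3], regcorr=[[0.5, 0.9, 0.9]])
        keep_above, _ = oe_qc_filter(ds, OeConfig(regcorr_direction="keep_above"))
        assert np.isnan(keep_above.log2_ratio.iloc[0, 0])
        keep_below, _ = oe_qc_filter(ds, OeConfig(regcorr_direction="keep_below"))
        assert keep_below.log2_ratio.iloc[0, 0] == 0.5
        assert np.isnan(keep_below.log2_ratio.iloc[0, 1])

    def test_sparse_genes_reported_untestable(self):
        ds = _oe_dataset([[0.5] * 3], sob={"c": [[1.0, 1.0, 2.5]]})
        _, report = oe_qc_filter(ds)
        assert report["untestable"] == ["G0"]


class TestGeneStats:
    def test_one_sample_t_worked_example(self):
        out = gene_stats(pd.DataFrame([[0.5, 0.6, 0.7]], index=["g"]))
        row = out.loc["g"]
        assert row["mean_log2"] == pytest.approx(0.6)
        assert row["t_stat"] == pytest.approx(10.392304845413266)
        assert row["p_value"] == pytest.approx(0.009132611386275451, rel=1e-9)

    def test_all_zero_gene_excluded_with_flag(self):
        out = gene_stats(pd.DataFrame([[0.0, 0.0, 0.0]], index=["g"]))
        row = out.loc["g"]
        assert row["fold_change"] == 1.0
        assert not row["tested"] and row["zero_variance"]

    def test_downregulated_fold(self):
        out = gene_stats(pd.DataFrame([[-0.8, -0.9, -1.0]], index=["g"]))
        assert out.loc["g", "fold_change"] == pytest.approx(2 ** -0.9)

    def test_zero_variance_nonzero_mean_flagged_zero_limit(self):
        out = gene_stats(pd.DataFrame([[0.5, 0.5, 0.5]], index=["g"]))
        row = out.loc["g"]
        assert row["zero_variance"] and row["p_value"] == 0.0 and row["tested"]


class TestChangedGenes:
    @pytest.fixture
    def stats_frame(self):
        return pd.DataFrame({
            "fold_change": [1.6, 0.60, 1.6, 0.70, 2.0],
            "p_value": [0.01, 0.03, 0.2, 0.01, 0.04],
            "tested": [True] * 5,
        }, index=["up1", "down1", "ns_p", "neither", "up2"])

    def test_thresholds(self, stats_frame):
        up, down = changed_genes(stats_frame, OeConfig())
        assert up == {"up1", "up2"}
        assert down == {"down1"}  # 0.70 > 1/1.5: not down

    def test_reciprocal_boundary(self):
        df = pd.DataFrame({"fold_change": [1 / 1.5], "p_value": [0.01],
                           "tested": [True]}, index=["g"])
        _, down = changed_genes(df, OeConfig())
        assert down == {"g"}


class TestTargetShift:
    def test_exact_mann_whitney_small_case(self):
        # targets' log2 ratios [1,2,3] vs non-targets [4,5,6]: U=0, p=2/20
        df = pd.DataFrame({"mean_log2": [1, 2, 3, 4, 5, 6],
                           "fold_change": 2.0 ** np.arange(1, 7),
                           "tested": [True] * 6},
                          index=list("abcdef"))
        res = target_shift(df, {"a", "b", "c"})
        assert res.mw_p == pytest.approx(0.1)

    def test_fold_change_conventions_reported(self):
        df = pd.DataFrame({"mean_log2": [-1.0, 1.0, 0.0, 0.0],
                           "fold_change": [0.5, 2.0, 1.0, 1.0],
                           "tested": [True] * 4}, index=list("abcd"))
        res = target_shift(df, {"a", "b"})
        assert res.mean_fc_targets == pytest.approx(1.25)   # arithmetic
        assert res.geom_fc_targets == pytest.approx(1.0)    # back-transformed

    def test_cdf_table_is_monotone(self):
        df, truth = gen_overexpression(500, 50, 0.9, "MAP1", 4.0, 3, 0.2, 4)
        res = target_shift(gene_stats(df), truth.true_targets)
        assert (np.diff(res.cdf_table["cdf_targets"]) >= 0).all()
        assert res.cdf_table["cdf_nontargets"].iloc[-1] == pytest.approx(1.0)

    def test_empty_group_raises(self):
        df = pd.DataFrame({"mean_log2": [0.0], "fold_change": [1.0],
                           "tested": [True]}, index=["a"])
        with pytest.raises(ValueError):
            target_shift(df, {"a"})

    def test_mw_invariant_under_monotone_transform(self, rng):
        x = rng.normal(0, 1, 40)
        df1 = pd.DataFrame({"mean_log2": x, "fold_change": 2.0 ** x,
                            "tested": [True] * 40},
                           index=[f"g{i}" for i in range(40)])
        y = np.exp(x)  # strictly increasing transform of the pooled values
        df2 = df1.assign(mean_log2=y)
        targets = {f"g{i}" for i in range(10)}
        assert target_shift(df1, targets).mw_p == pytest.approx(
            target_shift(df2, targets).mw_p, abs=1e-12)


class TestOverrepFisher:
    def test_worked_example(self):
        universe = {f"g{i}" for i in range(8)}
        targets = {"g0", "g1", "g2", "g3"}
        down = {"g0", "g1", "g2", "g4"}
        table, p = overrep_fisher(down, targets, universe)
        assert table == [[3, 1], [1, 3]]
        assert p == pytest.approx(34 / 70, abs=1e-12)

    def test_no_association_is_p_one(self):
        universe = {"a", "b", "c", "d"}
        table, p = overrep_fisher({"a", "c"}, {"a", "b"}, universe)
        assert table == [[1, 1], [1, 1]]
        assert p == pytest.approx(1.0)

    def test_transpose_symmetry(self, rng):
        for _ in range(20):
            t = rng.integers(0, 10, size=(2, 2))
            p1 = stats.fisher_exact(t).pvalue
            p2 = stats.fisher_exact(t.T).pvalue
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_matches_enumeration_for_small_margins(self, rng):
        for _ in range(200):
            table = rng.integers(0, 16, size=(2, 2))  # margins <= 30
            expected = fisher_two_sided_by_enumeration(table.tolist())
            got = float(stats.fisher_exact(table).pvalue)
            assert got == pytest.approx(expected, abs=1e-12), table
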