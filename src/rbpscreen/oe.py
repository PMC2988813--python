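"""Overexpression profiling and target-shift analysis.

Replicate overexpression/control log2-ratio profiles are QC-filtered
(signal-over-background in both channels, regression correlation of the
two-color spot fit), summarized per gene (mean log2 ratio, fold change,
one-sample t-test against no change), and thresholded into up/down changed
gene sets.  The target-shift analysis asks whether a protein's
experimentally defined mRNA target set is coordinately shifted relative to
all non-targets: a two-sided Mann-Whitney U test on per-gene mean log2
ratios, the mean fold change of the target set, and a Fisher exact test for
over-representation of targets among the down-regulated messages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import mann_whitney_p
from .config import OeConfig

logger = logging.getLogger("rbpscreen")


@dataclass
class OeDataset:
    """Replicate log2 ratios with optional per-spot QC fields.

    ``sob`` maps channel name -> gene x replicate S/B matrix;
    ``regression_correlation`` is a gene x replicate matrix.
    """

    log2_ratio: pd.DataFrame
    sob: Optional[Dict[str, pd.DataFrame]] = None
    regression_correlation: Optional[pd.DataFrame] = None


@dataclass
class ShiftResult:
    mean_fc_targets: float
    mean_fc_nontargets: float
    geom_fc_targets: float            # 2^(mean of mean-log2), logged alternative
    mw_p: float
    n_targets: int
    n_nontargets: int
    cdf_table: pd.DataFrame           # log2 grid with target / non-target CDFs
    fisher_table: Optional[List[List[int]]] = None
    fisher_p: Optional[float] = None
    changed_up: Set[str] = field(default_factory=set)
    changed_down: Set[str] = field(default_factory=set)


def oe_qc_filter(ds: OeDataset, cfg: OeConfig | None = None) -> tuple[OeDataset, dict]:
    """Mask spots failing S/B or regression-correlation QC.

    A spot must have S/B strictly above ``sob_min`` in *both* channels and
    a regression correlation on the kept side of ``regcorr_threshold``
    (direction configurable; the conventional reading keeps well-correlated
    spots).  Genes left with fewer than two replicates are excluded from
    testing (reported, not silently dropped).
    """
    cfg = cfg or OeConfig()
    ratios = ds.log2_ratio.copy()
    bad = pd.DataFrame(False, index=ratios.index, columns=ratios.columns)
    if ds.sob is not None:
        for ch, sob in ds.sob.items():
            bad |= ~(sob > cfg.sob_min)
    if ds.regression_correlation is not None:
        rc = ds.regression_correlation
        if cfg.regcorr_direction == "keep_above":
            bad |= ~(rc >= cfg.regcorr_threshold)
        else:
            bad |= ~(rc < cfg.regcorr_threshold)
    n_masked = int((bad & ratios.notna()).to_numpy().sum())
    ratios = ratios.mask(bad)
    untestable = list(ratios.index[ratios.notna().sum(axis=1) < 2])
    report = {"n_masked": n_masked, "n_untestable": len(untestable),
              "untestable": untestable}
    logger.info("oe_qc_filter: %d spots masked (S/B > %g both channels, "
                "regcorr %s %g), %d genes left untestable", n_masked,
                cfg.sob_min, cfg.regcorr_direction, cfg.regcorr_threshold,
                len(untestable))
    return OeDataset(ratios, ds.sob, ds.regression_correlation), report


def gene_stats(ds: OeDataset | pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean log2 ratio, fold change and one-sample t p-value.

    The two-sided one-sample t tests H0: mean log2 ratio = 0 with df = n-1.
    Fold change is 2^mean_log2; values below 1 are down-regulation.  Genes
    with fewer than two finite replicates are untested.  A gene with zero
    replicate variance but nonzero mean has a degenerate t (infinite); its
    p is reported as 0.0 with ``zero_variance`` flagged rather than
    silently — the all-zero case is untested.
    """
    ratios = ds.log2_ratio if isinstance(ds, OeDataset) else ds
    n = ratios.notna().sum(axis=1)
    mean = ratios.mean(axis=1, skipna=True)
    sd = ratios.std(axis=1, ddof=1, skipna=True)
    tested = n >= 2
    zero_var = tested & (sd == 0)
    degenerate = zero_var & (mean != 0)
    n_zero = int(zero_var.sum())
    if n_zero:
        logger.warning("gene_stats: %d genes with zero replicate variance "
                       "(%d with nonzero mean reported at the p->0 limit)",
                       n_zero, int(degenerate.sum()))

    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = pd.Series(np.nan, index=ratios.index)
    ok = tested & ~zero_var
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n[ok] - 1)
    p[degenerate] = 0.0
    t[zero_var & (mean == 0)] = np.nan
    out = pd.DataFrame({
        "n": n,
        "mean_log2": mean,
        "fold_change": np.power(2.0, mean),
        "sd": sd,
        "t_stat": t,
        "p_value": p,
        "tested": tested & ~(zero_var & (mean == 0)),
        "zero_variance": zero_var,
    })
    return out


def changed_genes(gstats: pd.DataFrame, cfg: OeConfig | None = None) -> Tuple[Set[str], Set[str]]:
    """Split tested genes into up / down sets at the fold and p thresholds.

    Up: fold >= fold_min; down: fold <= 1/fold_min (reciprocal symmetry);
    both require p < alpha_gene.
    """
    cfg = cfg or OeConfig()
    sig = gstats["tested"] & (gstats["p_value"] < cfg.alpha_gene)
    up = set(gstats.index[sig & (gstats["fold_change"] >= cfg.fold_min)])
    down = set(gstats.index[sig & (gstats["fold_change"] <= 1.0 / cfg.fold_min)])
    logger.info("changed_genes: %d up, %d down (fold >= %g or <= %g, p < %g)",
                len(up), len(down), cfg.fold_min, 1 / cfg.fold_min,
                cfg.alpha_gene)
    return up, down


def target_shift(
    gstats: pd.DataFrame,
    targets: Iterable[str],
    cdf_bin_width: float = 0.1,
) -> ShiftResult:
    """Compare a target set's expression shift against all non-targets.

    Mean fold change of the targets is the arithmetic mean of per-gene
    linear fold changes (2^mean-log2); the back-transformed alternative
    2^(mean of mean-log2) is also reported.  Significance is a two-sided
    Mann-Whitney U test on per-gene mean log2 ratios.  A cumulative-
    distribution table over a log2 grid is emitted for plotting.
    """
    targets = set(targets)
    tested = gstats[gstats["tested"]]
    t_mask = tested.index.isin(targets)
    tg, nt = tested[t_mask], tested[~t_mask]
    if len(tg) == 0 or len(nt) == 0:
        raise ValueError("both targets and non-targets must be non-empty "
                         "among tested genes")
    mw_p = mann_whitney_p(tg["mean_log2"], nt["mean_log2"])
    lo = float(min(tested["mean_log2"].min(), -1.0))
    hi = float(max(tested["mean_log2"].max(), 1.0))
    grid = np.arange(np.floor(lo / cdf_bin_width) * cdf_bin_width,
                     hi + cdf_bin_width, cdf_bin_width)
    cdf = pd.DataFrame({
        "log2_ratio": grid,
        "cdf_targets": [np.mean(tg["mean_log2"] <= g) for g in grid],
        "cdf_nontargets": [np.mean(nt["mean_log2"] <= g) for g in grid],
    })
    res = ShiftResult(
        mean_fc_targets=float(tg["fold_change"].mean()),
        mean_fc_nontargets=float(nt["fold_change"].mean()),
        geom_fc_targets=float(2.0 ** tg["mean_log2"].mean()),
        mw_p=mw_p,
        n_targets=len(tg),
        n_nontargets=len(nt),
        cdf_table=cdf,
    )
    logger.info("target_shift: mean target FC %.4f (geometric %.4f) over %d "
                "targets vs %d non-targets, Mann-Whitney p = %.3g",
                res.mean_fc_targets, res.geom_fc_targets, res.n_targets,
                res.n_nontargets, res.mw_p)
    return res


def overrep_fisher(
    changed_down: Iterable[str],
    targets: Iterable[str],
    universe: Iterable[str],
) -> tuple[List[List[int]], float]:
    """Fisher exact test: are targets over-represented among down genes?

    Table rows are target / non-target, columns down / not-down; the
    two-sided p sums all tables with point probability <= the observed
    (probability-mass method).
    """
    down, targets, universe = set(changed_down), set(targets), set(universe)
    if not targets <= universe or not down <= universe:
        raise ValueError("targets and changed_down must be subsets of universe")
    a = len(targets & down)
    b = len(targets - down)
    c = len(down - targets)
    d = len(universe - targets - down)
    table = [[a, b], [c, d]]
    p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    logger.info("overrep_fisher: table %s, p = %.3g", table, p)
    return table, p
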