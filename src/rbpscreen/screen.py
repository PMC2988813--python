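"""Binder selection from replicate protein-microarray probings.

Two selection modes are provided, mirroring the two probing designs:

* **Z-score mode** (single-RNA probes, e.g. a short localization element):
  a protein is a binder when its averaged net signal lies more than
  ``z_threshold`` standard deviations above the array center in every
  replicate.
* **Rank mode** (total RNA / mRNA probings, where absolute signal scales
  vary between replicates): each array's signals are converted to
  percentile ranks in (0, 1], the per-protein median rank across replicates
  is histogrammed, and the trough of the resulting bimodal distribution —
  background proteins versus consistently highly ranked binders — is taken
  as a conservative selection cutoff.

Rank-mode selection is invariant under any strictly increasing per-array
transform of the signals; Z-mode under positive affine transforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .config import ScreenConfig

logger = logging.getLogger("rbpscreen")


class DegenerateArrayError(ValueError):
    """An array has zero signal variance; Z-scores are undefined."""


class InsufficientDataError(ValueError):
    pass


class NoTroughError(ValueError):
    """No valley found in the median-rank histogram; supply cutoff_override."""


@dataclass
class RankProfile:
    """Per-array percentile ranks and the per-feature median rank."""

    ranks: pd.DataFrame            # feature x array, values in (0, 1] or NaN
    median_rank: pd.Series         # per feature, over arrays with data
    excluded: List[str]            # features below the presence requirement


@dataclass
class BinderSelection:
    selected: Set[str]
    cutoff_used: float
    score: pd.Series               # per-feature Z (replicate mean) or median rank
    mode: str                      # {"zscore", "rank"}


def percentile_rank(values: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Ascending tie-averaged percentile ranks in (0, 1].

    Ranks are divided by the count of finite values, so the maximum maps to
    exactly 1.0; missing values stay missing.  Invariant under strictly
    increasing transforms.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    n = int(finite.sum())
    if n < 2:
        raise InsufficientDataError("percentile_rank needs >= 2 finite values")
    out = np.full(x.shape, np.nan)
    out[finite] = rankdata(x[finite], method="average") / n
    return out


def zscore_select(table: pd.DataFrame, cfg: ScreenConfig | None = None) -> BinderSelection:
    """Select binders whose signal exceeds ``z_threshold`` SDs above center.

    Per array, Z_i = (x_i - center) / SD with the sample SD (ddof=1) over
    all finite values.  With ``require_all_replicates`` a feature must clear
    the threshold in every replicate where it has data (and have data in
    all); otherwise the replicate-mean Z is thresholded.  The reported score
    is always the replicate-mean Z.
    """
    cfg = cfg or ScreenConfig()
    if table.shape[1] < 1:
        raise ValueError("need at least one array")
    z = pd.DataFrame(index=table.index, columns=table.columns, dtype=float)
    for col in table.columns:
        x = table[col].astype(float)
        finite = x.dropna()
        if len(finite) < 3:
            raise InsufficientDataError(f"array {col!r} has < 3 finite values")
        sd = finite.std(ddof=1)
        if sd == 0:
            raise DegenerateArrayError(f"array {col!r} has zero signal variance")
        center = finite.median() if cfg.center == "median" else finite.mean()
        z[col] = (x - center) / sd
    if cfg.center == "mean":
        logger.warning("Z-score centering on the mean; the screen's operational "
                       "definition centers on the median")
    mean_z = z.mean(axis=1, skipna=True)
    if cfg.require_all_replicates:
        ok = (z > cfg.z_threshold).all(axis=1) & z.notna().all(axis=1)
    else:
        ok = mean_z > cfg.z_threshold
    selected = set(table.index[ok])
    logger.info("zscore_select: %d/%d features above Z>%g (%s)",
                len(selected), len(table), cfg.z_threshold,
                "all replicates" if cfg.require_all_replicates else "mean Z")
    return BinderSelection(selected, cfg.z_threshold, mean_z, "zscore")


def median_rank_profile(table: pd.DataFrame, cfg: ScreenConfig | None = None) -> RankProfile:
    """Percentile-rank each array, then take per-feature median ranks.

    Features with data in fewer than ``min_presence`` of the arrays are
    excluded from the profile and reported.
    """
    cfg = cfg or ScreenConfig()
    if table.shape[1] < 2:
        raise ValueError("need at least two arrays")
    ranks = pd.DataFrame(
        {col: percentile_rank(table[col].to_numpy()) for col in table.columns},
        index=table.index)
    presence = ranks.notna().mean(axis=1)
    excluded = list(table.index[presence < cfg.min_presence])
    kept = ranks.loc[presence >= cfg.min_presence]
    med = kept.median(axis=1, skipna=True)
    if excluded:
        logger.info("median_rank_profile: %d features below presence %.2f excluded",
                    len(excluded), cfg.min_presence)
    return RankProfile(ranks=kept, median_rank=med, excluded=excluded)


def _histogram(median_ranks: np.ndarray, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    nbins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, nbins + 1)
    counts, _ = np.histogram(median_ranks, bins=edges)
    return counts, edges


def find_trough_cutoff(
    median_ranks: Iterable[float], cfg: ScreenConfig | None = None,
    max_depth_ratio: float = 0.5,
) -> float:
    """Locate the valley of the bimodal median-rank distribution.

    The median ranks are histogrammed at ``hist_bin_width`` and lightly
    smoothed (5-bin moving average) to suppress Poisson noise; within the
    trough search interval the cutoff is the bin maximizing the *relative*
    valley depth 1 - c(b) / min(max count left of b, max count right of b),
    i.e. the dip that most completely separates the two modes.  Ties (an
    empty gap between the modes) resolve to the central tied bin, whose
    midpoint is returned.  A dip only counts as a trough when its bin
    holds fewer than ``max_depth_ratio`` times the smaller flanking mode —
    shallow noise dips in a unimodal histogram raise :class:`NoTroughError`
    instead.  ``cutoff_override`` bypasses detection entirely.
    """
    cfg = cfg or ScreenConfig()
    if cfg.cutoff_override is not None:
        logger.info("find_trough_cutoff: auto-detection bypassed, using "
                    "cutoff_override=%g", cfg.cutoff_override)
        return float(cfg.cutoff_override)
    mr = np.asarray([m for m in median_ranks if np.isfinite(m)], dtype=float)
    if mr.size < 100:
        raise InsufficientDataError(
            "need >= 100 median ranks for trough detection; set cutoff_override")
    counts, edges = _histogram(mr, cfg.hist_bin_width)
    # 5-bin moving average; edges shrink toward the available window
    kernel = np.ones(5)
    smooth = np.convolve(counts, kernel, mode="same") / \
        np.convolve(np.ones_like(counts, dtype=float), kernel, mode="same")
    lo, hi = cfg.trough_search_interval
    in_win = np.where((edges[:-1] >= lo) & (edges[1:] <= hi))[0]
    if in_win.size < 3:
        raise NoTroughError("search interval narrower than three bins")
    first, last = in_win[0], in_win[-1]

    best_depth = -np.inf
    best_bins: List[int] = []
    best_flank = 0.0
    for b in range(first + 1, last):
        flank = float(min(smooth[first:b].max(), smooth[b + 1:last + 1].max()))
        if flank <= 0:
            continue
        depth = 1.0 - smooth[b] / flank
        if depth > best_depth + 1e-12:
            best_depth, best_bins, best_flank = depth, [b], flank
        elif depth >= best_depth - 1e-12:
            best_bins.append(b)
    if not best_bins or best_depth <= 1.0 - max_depth_ratio:
        raise NoTroughError(
            "no valley found in the median-rank histogram (distribution looks "
            "unimodal in the search interval); supply cutoff_override")
    # ties: contiguous run of equally deep bins -> central bin of the run
    runs: List[List[int]] = [[best_bins[0]]]
    for b in best_bins[1:]:
        if b == runs[-1][-1] + 1:
            runs[-1].append(b)
        else:
            runs.append([b])
    run = max(runs, key=len)
    b = run[len(run) // 2]
    cutoff = float(0.5 * (edges[b] + edges[b + 1]))
    logger.info("find_trough_cutoff: valley at %.4f (relative depth %.2f, "
                "flanking mode %.1f)", cutoff, best_depth, best_flank)
    return cutoff


def select_binders(profile: RankProfile, cutoff: float) -> BinderSelection:
    """Features with median percentile rank strictly greater than the cutoff."""
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must lie in (0, 1)")
    sel = set(profile.median_rank.index[profile.median_rank > cutoff])
    logger.info("select_binders: %d features above cutoff %.3f", len(sel), cutoff)
    return BinderSelection(sel, cutoff, profile.median_rank, "rank")


def overlap_analysis(set_a: Set[str], set_b: Set[str]) -> Dict[str, float]:
    """Exact overlap arithmetic between two binder sets.

    Percentages are rounded to the nearest integer for reporting, as in a
    Venn-diagram summary.
    """
    a, b = set(set_a), set(set_b)
    inter, union = a & b, a | b
    out = {
        "n_a": len(a),
        "n_b": len(b),
        "n_intersection": len(inter),
        "n_union": len(union),
        "n_a_only": len(a - b),
        "n_b_only": len(b - a),
        "pct_a_in_b": round(100.0 * len(inter) / len(a)) if a else 0,
        "pct_b_in_a": round(100.0 * len(inter) / len(b)) if b else 0,
        "pct_a_only": round(100.0 * len(a - b) / len(a)) if a else 0,
        "pct_b_only": round(100.0 * len(b - a) / len(b)) if b else 0,
    }
    return out
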