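"""RIP-Chip target calling: IP replicates versus mock controls.

Transcripts co-purifying with a tagged protein are identified from two-color
array log2 ratios (isolate/extract) of a few independent affinity isolations
against several mock isolations from untagged cells.  Spots failing the
signal-over-background filter are masked, features measured in too few
arrays are dropped, and each remaining feature is tested with a regularized
(Cyber-T-style) t-statistic: the per-group variance is shrunk toward a local
prior estimated from features of similar mean signal,

    sigma_hat^2 = (nu0 * sigma0^2 + (n - 1) * s^2) / (nu0 + n - 2),

with prior weight ``nu0`` and a sliding window of ``w`` features for
``sigma0``.  A feature is a target when it is at least ``fold_min``-fold
enriched (geometric mean, i.e. mean of log2 ratios) with p below ``p_max``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import RipConfig

logger = logging.getLogger("rbpscreen")


class UndefinedVarianceError(ValueError):
    """Both groups constant with no prior weight; the t-statistic is undefined."""


@dataclass
class RipDataset:
    """Log2 ratios and QC fields for a set of IP and mock arrays."""

    log2_ratio: pd.DataFrame                 # feature x array
    group: pd.Series                         # array -> {"IP", "mock"}
    signal_over_background: Optional[pd.DataFrame] = None  # extract channel

    def __post_init__(self) -> None:
        missing = set(self.log2_ratio.columns) - set(self.group.index)
        if missing:
            raise ValueError(f"arrays without group labels: {sorted(missing)}")

    @property
    def ip_arrays(self) -> List[str]:
        return [a for a in self.log2_ratio.columns if self.group[a] == "IP"]

    @property
    def mock_arrays(self) -> List[str]:
        return [a for a in self.log2_ratio.columns if self.group[a] == "mock"]

    @property
    def n_ip(self) -> int:
        return len(self.ip_arrays)

    @property
    def n_mock(self) -> int:
        return len(self.mock_arrays)


@dataclass
class QcReport:
    n_masked: int
    n_features_in: int
    n_features_dropped: int
    dropped: List[str] = field(default_factory=list)


def qc_filter(ds: RipDataset, cfg: RipConfig | None = None) -> tuple[RipDataset, QcReport]:
    """Mask low-S/B spots and drop features measured in too few arrays.

    A spot is masked when its extract-channel signal-over-background is not
    strictly above ``sob_min`` (a spot at exactly the threshold is masked).
    A feature is retained only if it has data in strictly more than
    ``presence_min`` of the arrays.
    """
    cfg = cfg or RipConfig()
    ratios = ds.log2_ratio.copy()
    n_masked = 0
    if ds.signal_over_background is not None:
        bad = ~(ds.signal_over_background > cfg.sob_min)
        n_masked = int((bad & ratios.notna()).to_numpy().sum())
        ratios = ratios.mask(bad)
    presence = ratios.notna().mean(axis=1)
    keep = presence > cfg.presence_min
    dropped = list(ratios.index[~keep])
    out = RipDataset(ratios.loc[keep], ds.group,
                     None if ds.signal_over_background is None
                     else ds.signal_over_background.loc[keep])
    report = QcReport(n_masked, len(ratios), len(dropped), dropped)
    logger.info("qc_filter: %d spots masked (S/B <= %g), %d/%d features dropped "
                "(presence <= %.0f%%)", n_masked, cfg.sob_min,
                len(dropped), len(ratios), 100 * cfg.presence_min)
    return out, report


def local_sd_prior(means: np.ndarray, sds: np.ndarray, w: int) -> np.ndarray:
    """Sliding-window prior SD over features sorted by mean signal.

    Features are ordered by mean; sigma0 for each feature is the average of
    the sample SDs in the window of ``w`` features centered on it.  Windows
    are truncated at the ends by clamping (the first and last features share
    the first/last full window), so every window has exactly ``w`` members
    when at least ``w`` features have a defined SD; with fewer, the window
    is the whole set.  Features with undefined SD get an undefined prior.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    out = np.full(means.shape, np.nan)
    ok = np.isfinite(means) & np.isfinite(sds)
    idx = np.where(ok)[0]
    if idx.size == 0:
        return out
    order = idx[np.argsort(means[idx], kind="stable")]
    s_sorted = sds[order]
    n = order.size
    ww = min(w, n)
    half = ww // 2
    csum = np.concatenate([[0.0], np.cumsum(s_sorted)])
    prior = np.empty(n)
    for i in range(n):
        start = min(max(i - half, 0), n - ww)
        prior[i] = (csum[start + ww] - csum[start]) / ww
    out[order] = prior
    return out


def regularized_t(
    ip: np.ndarray,
    mock: np.ndarray,
    sigma0_ip: float,
    sigma0_mock: float,
    nu0: int,
    cybert_df: bool = True,
) -> tuple[float, float, float]:
    """Cyber-T-style regularized two-sample t-test.

    Returns (t, df, two-sided p).  With ``nu0=0`` this reduces exactly to
    the Welch statistic with per-group sample variances (df then
    n1 + n2 - 2); with ``nu0>0`` each group's variance is shrunk toward its
    prior and the degrees of freedom are augmented by 2*nu0.
    """
    ip = np.asarray(ip, dtype=float)
    mock = np.asarray(mock, dtype=float)
    ip = ip[np.isfinite(ip)]
    mock = mock[np.isfinite(mock)]
    if len(ip) < 2 or len(mock) < 2:
        raise ValueError("need >= 2 finite values per group")

    def posterior_var(x: np.ndarray, s0: float) -> float:
        n = len(x)
        s2 = float(np.var(x, ddof=1))
        if nu0 == 0:
            # prior off: plain sample variance (ordinary Welch-style t);
            # a zero pooled variance is caught below
            return s2
        return (nu0 * s0 ** 2 + (n - 1) * s2) / (nu0 + n - 2)

    v_ip = posterior_var(ip, sigma0_ip)
    v_mock = posterior_var(mock, sigma0_mock)
    se = np.sqrt(v_ip / len(ip) + v_mock / len(mock))
    if se == 0:
        raise UndefinedVarianceError("zero pooled variance in both groups")
    t = float((ip.mean() - mock.mean()) / se)
    df = len(ip) + len(mock) - 2 + (2 * nu0 if cybert_df else 0)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, float(df), min(p, 1.0)


def call_targets(
    ds: RipDataset,
    cfg: RipConfig | None = None,
    self_id: Optional[str] = None,
) -> pd.DataFrame:
    """Call RIP-Chip targets from a QC-filtered dataset.

    Per feature: group means of available log2 ratios, fold change
    2^(mean_ip - mean_mock), regularized-t p-value using a per-group local
    SD prior.  A feature is a target when fold_change >= fold_min and
    p < p_max.  Features with fewer than two values in either group are
    excluded (column ``tested`` False).  Output sorted by descending fold
    change; ``is_self`` marks the tagged protein's own transcript among the
    targets.
    """
    cfg = cfg or RipConfig()
    ip_cols, mock_cols = ds.ip_arrays, ds.mock_arrays
    if len(ip_cols) < 2 or len(mock_cols) < 2:
        raise ValueError("need >= 2 IP and >= 2 mock arrays")
    ip = ds.log2_ratio[ip_cols]
    mock = ds.log2_ratio[mock_cols]

    mean_ip = ip.mean(axis=1, skipna=True)
    mean_mock = mock.mean(axis=1, skipna=True)
    n_ip = ip.notna().sum(axis=1)
    n_mock = mock.notna().sum(axis=1)
    sd_ip = ip.std(axis=1, ddof=1, skipna=True)
    sd_mock = mock.std(axis=1, ddof=1, skipna=True)
    tested = (n_ip >= 2) & (n_mock >= 2)

    s0_ip = local_sd_prior(mean_ip.to_numpy(), sd_ip.to_numpy(), cfg.window_size)
    s0_mock = local_sd_prior(mean_mock.to_numpy(), sd_mock.to_numpy(),
                             cfg.window_size)

    # vectorized form of regularized_t (same closed form, per feature)
    feats = ds.log2_ratio.index
    nu0 = cfg.prior_df

    def post_var(s0: np.ndarray, sd: pd.Series, n: pd.Series) -> np.ndarray:
        s2 = sd.to_numpy() ** 2
        if nu0 == 0:  # prior off: plain sample variance
            return s2
        nn = n.to_numpy().astype(float)
        return (nu0 * s0 ** 2 + (nn - 1) * s2) / (nu0 + nn - 2)

    v_ip = post_var(s0_ip, sd_ip, n_ip)
    v_mock = post_var(s0_mock, sd_mock, n_mock)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(v_ip / n_ip.to_numpy() + v_mock / n_mock.to_numpy())
        t = (mean_ip.to_numpy() - mean_mock.to_numpy()) / se
    df_arr = n_ip.to_numpy() + n_mock.to_numpy() - 2 \
        + (2 * nu0 if cfg.cybert_df else 0)
    mask = tested.to_numpy() & np.isfinite(t)
    p = np.full(len(feats), np.nan)
    p[mask] = np.minimum(2.0 * stats.t.sf(np.abs(t[mask]), df_arr[mask]), 1.0)
    t = np.where(mask, t, np.nan)

    fold = np.power(2.0, mean_ip - mean_mock)
    out = pd.DataFrame({
        "mean_log2_ip": mean_ip,
        "mean_log2_mock": mean_mock,
        "fold_change": fold,
        "t_stat": t,
        "p_value": p,
        "df": np.where(tested, df_arr, np.nan),
        "tested": tested,
    }, index=feats)
    out["is_target"] = (out["tested"] & (out["fold_change"] >= cfg.fold_min)
                        & (out["p_value"] < cfg.p_max))
    out["is_self"] = out["is_target"] & (out.index == self_id) \
        if self_id is not None else False
    out = out.sort_values("fold_change", ascending=False)
    n_excl = int((~tested).sum())
    logger.info("call_targets: %d features tested (%d excluded, <2 values per "
                "group), %d targets (fold >= %g, p < %g)",
                int(tested.sum()), n_excl, int(out['is_target'].sum()),
                cfg.fold_min, cfg.p_max)
    return out
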