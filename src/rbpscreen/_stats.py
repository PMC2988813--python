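"""Shared statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats


def mann_whitney_p(x, y, max_exact: int = 50) -> float:
    """Two-sided Mann-Whitney U p-value, exact when cheaply possible.

    The exact null distribution is used when both groups are small enough
    and the pooled values carry no ties; otherwise the normal approximation
    with continuity and tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and max(len(x), len(y)) <= max_exact) \
        else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method).pvalue)
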