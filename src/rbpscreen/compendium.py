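"""Expression-compendium clustering and class comparisons.

Candidate-RBP expression profiles across many conditions (RMA-scale log
expression) are grouped by K-means (Lloyd's algorithm, Euclidean distance,
multiple restarts keeping the lowest within-cluster sum of squares) to
expose expression regimes — ubiquitously high, ubiquitously low,
condition-specific.  Expression-level populations of two gene classes are
compared on per-gene median expression with a two-sided Wilcoxon rank-sum
test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List

import pandas as pd
from sklearn.cluster import KMeans

from ._stats import mann_whitney_p

logger = logging.getLogger("rbpscreen")


@dataclass
class ClusterResult:
    assignment: pd.Series       # gene -> cluster index
    centroids: pd.DataFrame     # cluster x condition
    inertia: float              # within-cluster sum of squares


def load_expression_matrix(df: pd.DataFrame) -> tuple[pd.DataFrame, List[str]]:
    """Drop genes with any missing condition value; report them."""
    incomplete = list(df.index[df.isna().any(axis=1)])
    if incomplete:
        logger.info("expression matrix: %d genes with missing profiles dropped",
                    len(incomplete))
    return df.dropna(axis=0), incomplete


def kmeans_profiles(
    m: pd.DataFrame, k: int = 10, seed: int = 0, n_restarts: int = 25,
) -> ClusterResult:
    """Cluster genes by their condition profiles with K-means.

    Lloyd's algorithm with Euclidean distance, k-means++ seeding,
    ``n_restarts`` restarts keeping the lowest within-cluster sum of
    squares; deterministic for a fixed seed.
    """
    if k > len(m):
        raise ValueError("k must not exceed the number of genes")
    m2, dropped = load_expression_matrix(m)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=int(seed),
                algorithm="lloyd")
    labels = km.fit_predict(m2.to_numpy())
    assignment = pd.Series(labels, index=m2.index, name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_, columns=m2.columns)
    centroids.index.name = "cluster"
    sizes = assignment.value_counts().sort_index()
    logger.info("kmeans_profiles: k=%d, inertia %.2f, cluster sizes %s",
                k, km.inertia_, sizes.to_dict())
    return ClusterResult(assignment, centroids, float(km.inertia_))


def cluster_summary(res: ClusterResult) -> pd.DataFrame:
    """Cluster sizes and centroid ranges (the heatmap's numeric summary)."""
    sizes = res.assignment.value_counts().sort_index()
    return pd.DataFrame({
        "n_genes": sizes,
        "centroid_min": res.centroids.min(axis=1),
        "centroid_max": res.centroids.max(axis=1),
        "centroid_mean": res.centroids.mean(axis=1),
    })


def class_expression_test(
    m: pd.DataFrame, class_a: Iterable[str], class_b: Iterable[str],
) -> tuple[float, float, float]:
    """Compare expression levels of two disjoint gene classes.

    Per gene, the median expression across conditions; then a two-sided
    Wilcoxon rank-sum (Mann-Whitney U) test between the two populations of
    medians.  Returns (median-of-medians A, median-of-medians B, p).
    """
    a, b = set(class_a), set(class_b)
    if a & b:
        raise ValueError("gene classes must be disjoint")
    med = m.median(axis=1)
    ma = med[med.index.isin(a)]
    mb = med[med.index.isin(b)]
    if len(ma) == 0 or len(mb) == 0:
        raise ValueError("both classes must be represented in the matrix")
    p = mann_whitney_p(ma, mb)
    return float(ma.median()), float(mb.median()), p
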