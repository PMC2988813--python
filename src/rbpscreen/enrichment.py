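"""Hypergeometric over-representation tests with Bonferroni correction.

Given a sample of genes (e.g. selected RNA binders, or one protein's RIP
targets), an explicit universe (e.g. all proteins on the array, or all
features with array data), and a gene→term annotation (GO process /
function / compartment namespaces, or Pfam domain membership), each term
with at least one hit in the sample is tested for over-representation with
the exact hypergeometric upper tail

    P(X >= k),  X ~ Hypergeom(N, K, n)

where N is the universe size, K the term's genes in the universe, n the
sample size and k the term's genes in the sample.  The Bonferroni
multiplier is the number of terms actually tested in the namespace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Set

import pandas as pd
from scipy.stats import hypergeom

from .config import EnrichConfig

logger = logging.getLogger("rbpscreen")

NAMESPACES = ("process", "function", "compartment", "pfam")


@dataclass
class AnnotationMap:
    """Gene→term and term→gene maps for one namespace."""

    namespace: str
    gene_to_terms: Dict[str, Set[str]] = field(default_factory=dict)
    term_to_genes: Dict[str, Set[str]] = field(default_factory=dict)
    term_names: Dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_table(cls, table: pd.DataFrame, namespace: str) -> "AnnotationMap":
        """Build from an annotation table (gene_id, namespace, term_id, term_name)."""
        if namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace {namespace!r}")
        sub = table[table["namespace"] == namespace]
        am = cls(namespace)
        for gene, term, name in zip(sub["gene_id"], sub["term_id"],
                                    sub["term_name"]):
            am.gene_to_terms.setdefault(gene, set()).add(term)
            am.term_to_genes.setdefault(term, set()).add(gene)
            am.term_names.setdefault(term, name)
        return am


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    N: universe size, K: property carriers in the universe, n: sample size,
    k: property carriers in the sample.  Computed in log space by scipy, so
    it is stable for universes of thousands of genes.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid hypergeometric bounds N={N} K={K} n={n} k={k}")
    if k > K:
        return 0.0
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_terms(
    sample: Iterable[str],
    annotation: AnnotationMap,
    cfg: EnrichConfig | None = None,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Test every term with >= 1 sample hit for over-representation.

    The universe is explicit; annotation genes outside it are ignored.
    Returns a DataFrame sorted by raw p with columns term_id, term_name,
    k, n, K, N, p_raw, p_corrected, significant.
    """
    cfg = cfg or EnrichConfig()
    sample = set(sample)
    if universe is None:
        raise ValueError("an explicit universe is required")
    universe = set(universe)
    if not sample or not universe:
        raise ValueError("sample and universe must be non-empty")
    if not sample <= universe:
        raise ValueError("sample must be a subset of the universe")
    N, n = len(universe), len(sample)

    records = []
    for term, genes in annotation.term_to_genes.items():
        in_universe = genes & universe
        k = len(in_universe & sample)
        if k < 1:
            continue
        K = len(in_universe)
        records.append((term, annotation.term_names.get(term, term),
                        k, n, K, N, hypergeom_upper_tail(N, K, n, k)))
    n_tested = len(records)
    logger.info("enrich_terms[%s]: %d terms tested (k >= 1), universe %d, "
                "sample %d, correction=%s", annotation.namespace, n_tested,
                N, n, cfg.correction)
    df = pd.DataFrame(records, columns=["term_id", "term_name", "k", "n",
                                        "K", "N", "p_raw"])
    if cfg.correction == "bonferroni":
        df["p_corrected"] = (df["p_raw"] * n_tested).clip(upper=1.0)
    else:
        df["p_corrected"] = df["p_raw"]
    df["significant"] = df["p_corrected"] < cfg.alpha
    return df.sort_values("p_raw", kind="stable").reset_index(drop=True)
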