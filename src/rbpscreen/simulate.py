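"""Synthetic data with known ground truth for every pipeline stage.

Each generator emulates one of the screen's input classes:

* :func:`gen_protoarray` — replicate protein-microarray scans with a set of
  spike-in binders that are consistently highly ranked across replicates, on
  a log-normal background of non-binders.
* :func:`gen_ripchip` — IP vs mock two-color log2-ratio datasets with
  spike-in enriched transcripts and low-S/B spots to exercise QC.
* :func:`gen_overexpression` — triplicate overexpression profiles with a
  strongly induced driver gene and a small coordinated negative shift of a
  target set.
* :func:`gen_compendium` — a block-structured genes x conditions expression
  matrix for clustering.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` child seeds, so identical calls are
byte-identical.  Background fluorescence intensities are log-normal
(strictly positive, right-skewed); log2 ratios are Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set

import numpy as np
import pandas as pd

from .io import ArrayScan, SpotRecord
from .ripchip import RipDataset

# offsets for per-generator child seeds
_PROTO, _RIP, _OE, _COMP = 11, 13, 17, 19


@dataclass
class SimTruth:
    """Ground truth attached to a simulated dataset."""

    true_binders: Set[str] = field(default_factory=set)
    true_targets: Set[str] = field(default_factory=set)
    true_shift: Optional[float] = None
    cluster_assignment: Dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "true_binders": sorted(self.true_binders),
            "true_targets": sorted(self.true_targets),
            "true_shift": self.true_shift,
            "cluster_assignment": dict(sorted(self.cluster_assignment.items())),
            "seed": self.seed,
        }


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _feature_ids(n: int, prefix: str) -> List[str]:
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def gen_protoarray(
    n_proteins: int,
    n_replicates: int,
    binder_fraction: float,
    binder_rank_floor: float,
    noise_sd: float,
    seed: int,
    n_spots: int = 2,
    channel_names: Iterable[str] = ("Cy3", "Cy5"),
    shared_binders: bool = True,
    log_mu: float = 6.0,
    log_sigma: float = 1.0,
) -> tuple[List[ArrayScan], SimTruth]:
    """Simulate replicate protein-microarray scans with spike-in binders.

    Non-binders draw i.i.d. log-normal net signals per replicate and channel.
    Binders are injected by rank: each binder's latent signal sits at a
    quantile level drawn uniformly from [binder_rank_floor, 1) of the
    *background* log-normal law, fixed per binder and re-noised per
    replicate with multiplicative log-normal noise of scale ``noise_sd``.
    Duplicate spots add independent noise of the same scale.

    With B = binder_fraction the realized full-array percentile rank of the
    weakest binder is therefore ~ binder_rank_floor * (1 - B): the floor is
    a quantile of the background distribution, not of the mixed array.

    Returns one :class:`ArrayScan` per replicate plus the ground truth.
    """
    if n_proteins < 10:
        raise ValueError("n_proteins must be >= 10")
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    n_binders = int(round(binder_fraction * n_proteins))
    if n_binders < 1:
        raise ValueError("binder_fraction yields < 1 binder")
    rng = _rng(seed, _PROTO)
    channel_names = list(channel_names)
    ids = _feature_ids(n_proteins, "YP")

    binder_idx: Dict[str, np.ndarray] = {}
    shared = rng.choice(n_proteins, size=n_binders, replace=False)
    for ch in channel_names:
        if shared_binders:
            binder_idx[ch] = shared
        else:
            binder_idx[ch] = rng.choice(n_proteins, size=n_binders, replace=False)

    # latent binder quantile levels, fixed across replicates
    levels = {ch: rng.uniform(binder_rank_floor, 1.0, size=n_binders)
              for ch in channel_names}

    def background_ppf(q: np.ndarray) -> np.ndarray:
        # quantile function of the log-normal background
        from scipy.stats import norm
        return np.exp(log_mu + log_sigma * norm.ppf(q))

    scans: List[ArrayScan] = []
    for r in range(n_replicates):
        base = {}
        for ch in channel_names:
            sig = np.exp(rng.normal(log_mu, log_sigma, size=n_proteins))
            binder_sig = background_ppf(levels[ch])
            if noise_sd > 0:
                binder_sig = binder_sig * np.exp(
                    rng.normal(0.0, noise_sd, size=n_binders))
            sig[binder_idx[ch]] = binder_sig
            base[ch] = sig
        records: List[SpotRecord] = []
        for i, fid in enumerate(ids):
            for s in range(1, n_spots + 1):
                net = {}
                for ch in channel_names:
                    v = base[ch][i]
                    if noise_sd > 0:
                        v = v * np.exp(rng.normal(0.0, noise_sd))
                    net[ch] = float(v)
                records.append(SpotRecord(fid, s, net, flag=0))
        scans.append(ArrayScan(f"rep{r + 1}", records, channel_names))

    truth = SimTruth(
        true_binders={ids[i] for i in binder_idx[channel_names[0]]},
        seed=seed,
    )
    return scans, truth


def gen_ripchip(
    n_features: int,
    n_targets: int,
    log2_enrichment: float,
    n_ip: int,
    n_mock: int,
    noise_sd: float,
    sob_low_fraction: float,
    seed: int,
    sob_threshold: float = 1.8,
) -> tuple[RipDataset, SimTruth]:
    """Simulate a RIP-Chip dataset: IP replicates vs mock controls.

    Non-target log2 ratios are Normal(0, noise_sd) in both groups; targets
    get their IP ratios shifted by ``log2_enrichment``.  A
    ``sob_low_fraction`` of spots per array is assigned signal-over-
    background below ``sob_threshold`` so the QC filter has work to do.
    """
    if n_ip < 2 or n_mock < 2:
        raise ValueError("need n_ip >= 2 and n_mock >= 2")
    if not (0 <= n_targets <= n_features):
        raise ValueError("n_targets must lie in [0, n_features]")
    rng = _rng(seed, _RIP)
    ids = _feature_ids(n_features, "ORF")
    arrays = [f"IP{i + 1}" for i in range(n_ip)] + \
             [f"MOCK{i + 1}" for i in range(n_mock)]
    groups = pd.Series(["IP"] * n_ip + ["mock"] * n_mock, index=arrays)

    target_pos = rng.choice(n_features, size=n_targets, replace=False) \
        if n_targets else np.array([], dtype=int)
    ratios = rng.normal(0.0, noise_sd, size=(n_features, n_ip + n_mock))
    if n_targets:
        ratios[target_pos, :n_ip] += log2_enrichment

    # S/B of the extract (input) channel: mostly comfortably above threshold
    sob = np.exp(rng.normal(np.log(8.0), 0.8, size=(n_features, n_ip + n_mock)))
    sob = np.maximum(sob, sob_threshold + 0.01)
    n_low = int(round(sob_low_fraction * n_features))
    for j in range(n_ip + n_mock):
        if n_low:
            low = rng.choice(n_features, size=n_low, replace=False)
            sob[low, j] = rng.uniform(0.5, sob_threshold, size=n_low)

    log2_ratio = pd.DataFrame(ratios, index=pd.Index(ids, name="feature_id"),
                              columns=arrays)
    sob_df = pd.DataFrame(sob, index=log2_ratio.index, columns=arrays)
    ds = RipDataset(log2_ratio=log2_ratio, group=groups,
                    signal_over_background=sob_df)
    truth = SimTruth(true_targets={ids[i] for i in target_pos}, seed=seed)
    return ds, truth


def gen_overexpression(
    n_genes: int,
    target_ids,
    target_mean_fc: float,
    driver_id: str,
    driver_fc: float,
    n_reps: int,
    noise_sd: float,
    seed: int,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate replicate overexpression/control log2-ratio profiles.

    ``target_ids`` may be an explicit iterable of gene IDs or an integer
    count (targets then drawn at random among simulated genes, never the
    driver).  Non-targets center at log2 ratio 0, targets at
    log2(target_mean_fc), the driver at log2(driver_fc); each of the
    ``n_reps`` replicate columns adds i.i.d. Gaussian noise.
    """
    rng = _rng(seed, _OE)
    ids = _feature_ids(n_genes, "G")
    if driver_id not in ids:
        ids[0] = driver_id
    if isinstance(target_ids, int):
        pool = [g for g in ids if g != driver_id]
        targets = set(rng.choice(pool, size=target_ids, replace=False))
    else:
        targets = set(target_ids)
    if driver_id in targets:
        raise ValueError("driver_id must not be in target_ids")
    unknown = targets - set(ids)
    if unknown:
        raise ValueError(f"target IDs not among simulated genes: {sorted(unknown)[:3]}")

    mu = np.zeros(n_genes)
    tmask = np.array([g in targets for g in ids])
    mu[tmask] = np.log2(target_mean_fc)
    mu[ids.index(driver_id)] = np.log2(driver_fc)
    data = mu[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_reps))
    df = pd.DataFrame(data, index=pd.Index(ids, name="gene_id"),
                      columns=[f"rep{i + 1}" for i in range(n_reps)])
    truth = SimTruth(true_targets=targets, true_shift=target_mean_fc, seed=seed)
    return df, truth


def gen_compendium(
    n_genes: int,
    n_conditions: int,
    n_clusters: int,
    separation: float,
    seed: int,
    noise_sd: float = 1.0,
    baseline: float = 8.0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a block-structured RMA-scale expression compendium.

    Genes are partitioned into ``n_clusters`` equal-size blocks; each block
    follows its own condition-profile mean (centroid entries ~
    Normal(baseline, separation^2)) plus Gaussian noise of scale
    ``noise_sd``.  ``separation=0`` collapses all blocks onto the baseline.
    """
    if n_clusters > n_genes:
        raise ValueError("n_clusters must be <= n_genes")
    rng = _rng(seed, _COMP)
    ids = _feature_ids(n_genes, "G")
    assignment = np.repeat(np.arange(n_clusters),
                           int(np.ceil(n_genes / n_clusters)))[:n_genes]
    centroids = baseline + rng.normal(0.0, 1.0, size=(n_clusters, n_conditions)) \
        * separation
    data = centroids[assignment] + rng.normal(0.0, noise_sd,
                                              size=(n_genes, n_conditions))
    df = pd.DataFrame(data, index=pd.Index(ids, name="gene_id"),
                      columns=[f"cond{i + 1}" for i in range(n_conditions)])
    truth = SimTruth(cluster_assignment={g: int(c) for g, c
                                         in zip(ids, assignment)}, seed=seed)
    return df, truth
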