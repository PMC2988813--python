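"""Pipeline configuration.

Every stage of the screen exposes its thresholds through a small dataclass;
:class:`PipelineConfig` bundles them together with the global seed and can be
loaded from a YAML key-value file.  Defaults are the operating points of the
published screen (Z > 3.5, signal-over-background > 1.8, 3-fold / p < 0.01
target calling, Bonferroni alpha 0.01, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Tuple

import yaml


@dataclass
class ScreenConfig:
    """Settings for the protein-microarray binder selection."""

    z_threshold: float = 3.5
    center: str = "median"  # {"median", "mean"} — centering of the Z statistic
    require_all_replicates: bool = True
    hist_bin_width: float = 0.01
    trough_search_interval: Tuple[float, float] = (0.5, 1.0)
    cutoff_override: Optional[float] = None
    min_presence: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.hist_bin_width < 0.1):
            raise ValueError("hist_bin_width must lie in (0, 0.1)")
        lo, hi = self.trough_search_interval
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("trough_search_interval must be within [0, 1]")
        if self.center not in ("median", "mean"):
            raise ValueError("center must be 'median' or 'mean'")


@dataclass
class RipConfig:
    """Settings for RIP-Chip target calling (QC + regularized t-test)."""

    sob_min: float = 1.8          # spots kept only if S/B strictly above this
    presence_min: float = 0.6     # feature kept only if data in > 60% of arrays
    fold_min: float = 3.0
    p_max: float = 0.01
    prior_df: int = 10            # nu0, weight of the local variance prior
    window_size: int = 101        # w, width of the sliding SD-prior window
    cybert_df: bool = True        # df = n1+n2-2+2*nu0 (Cyber-T) vs n1+n2-2

    def __post_init__(self) -> None:
        if self.fold_min <= 1:
            raise ValueError("fold_min must exceed 1")
        if not (0 < self.p_max < 1):
            raise ValueError("p_max must lie in (0, 1)")
        if self.prior_df < 0:
            raise ValueError("prior_df must be >= 0")
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ValueError("window_size must be a positive odd integer")


@dataclass
class OeConfig:
    """Settings for overexpression profiling."""

    sob_min: float = 2.0
    regcorr_threshold: float = 0.6
    regcorr_direction: str = "keep_above"  # {"keep_above", "keep_below"}
    fold_min: float = 1.5
    alpha_gene: float = 0.05

    def __post_init__(self) -> None:
        if self.fold_min <= 1:
            raise ValueError("fold_min must exceed 1")
        if self.regcorr_direction not in ("keep_above", "keep_below"):
            raise ValueError("regcorr_direction must be keep_above/keep_below")


@dataclass
class EnrichConfig:
    """Settings for hypergeometric term enrichment."""

    alpha: float = 0.01
    correction: str = "bonferroni"  # {"bonferroni", "none"}

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.correction not in ("bonferroni", "none"):
            raise ValueError("correction must be 'bonferroni' or 'none'")


@dataclass
class PipelineConfig:
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    rip: RipConfig = field(default_factory=RipConfig)
    oe: OeConfig = field(default_factory=OeConfig)
    enrich: EnrichConfig = field(default_factory=EnrichConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file.

    Unknown keys raise; sections may be partial, missing values keep their
    defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sections = {
        "screen": ScreenConfig,
        "rip": RipConfig,
        "oe": OeConfig,
        "enrich": EnrichConfig,
    }
    kwargs: dict = {}
    for key, value in raw.items():
        if key == "seed":
            kwargs["seed"] = int(value)
        elif key in sections:
            sub = dict(value or {})
            if "trough_search_interval" in sub:
                sub["trough_search_interval"] = tuple(sub["trough_search_interval"])
            kwargs[key] = sections[key](**sub)
        else:
            raise ValueError(f"unknown configuration section: {key!r}")
    return PipelineConfig(**kwargs)
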