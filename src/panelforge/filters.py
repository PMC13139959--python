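"""Hard-filter cascade for discovery genotype matrices.

Stage order is fixed: per-call quality mask (depth >= 10, GQ >= 30, both
boundaries inclusive) -> heterozygote allele-balance mask (ref-read fraction
kept inside [0.25, 0.75]) -> minor-allele-count filter (MAC >= 2 over
post-masking calls) -> per-locus missingness filter (missing fraction <= 0.5).
Calls are only ever changed to missing; loci are only ever dropped; applying
the cascade twice equals applying it once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "FilterReport",
    "mask_low_quality_calls",
    "filter_allele_balance",
    "filter_loci",
]


@dataclass
class FilterConfig:
    min_mac: int = 2
    min_depth: float = 10
    min_gq: float = 30
    max_locus_missing: float = 0.5
    allele_balance_range: tuple[float, float] = (0.25, 0.75)
    max_sample_missing: float | None = None  # optional per-sample cutoff, off by default

    def __post_init__(self) -> None:
        if self.min_mac < 0 or self.min_depth < 0 or self.min_gq < 0:
            raise ValueError("thresholds must be non-negative")
        lo, hi = self.allele_balance_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("allele balance range must lie within [0, 1]")
        if not (0 <= self.max_locus_missing <= 1):
            raise ValueError("max_locus_missing must be in [0, 1]")


@dataclass
class FilterReport:
    """Per-stage bookkeeping; locus counts are non-increasing down the cascade."""

    stages: list[dict] = field(default_factory=list)

    def add(self, stage: str, loci_in: int, loci_out: int, calls_masked: int = 0) -> None:
        self.stages.append(
            {"stage": stage, "loci_in": loci_in, "loci_out": loci_out,
             "calls_masked": calls_masked}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)


def mask_low_quality_calls(m: GenotypeMatrix, cfg: FilterConfig | None = None) -> GenotypeMatrix:
    """Set calls with depth < min_depth or GQ < min_gq to missing.

    A logged no-op when the corresponding metadata is absent.
    """
    cfg = cfg or FilterConfig()
    out = m.copy()
    called = out.codes != MISSING
    mask = np.zeros_like(called)
    if out.depth is not None:
        mask |= called & (np.nan_to_num(out.depth, nan=np.inf) < cfg.min_depth)
    else:
        logger.info("no depth metadata; depth mask skipped")
    if out.quality is not None:
        mask |= called & (np.nan_to_num(out.quality, nan=np.inf) < cfg.min_gq)
    else:
        logger.info("no genotype-quality metadata; GQ mask skipped")
    out.codes[mask] = MISSING
    return out


def filter_allele_balance(m: GenotypeMatrix, cfg: FilterConfig | None = None) -> GenotypeMatrix:
    """Mask heterozygous calls whose ref-read fraction falls outside the range.

    The rule applies only to calls made as heterozygous; homozygous calls are
    untouched regardless of their read ratios.  Boundary values are retained.
    """
    cfg = cfg or FilterConfig()
    out = m.copy()
    if out.allele_depths is None:
        logger.info("no allele-depth metadata; allele-balance filter skipped")
        return out
    lo, hi = cfg.allele_balance_range
    ref = out.allele_depths[:, :, 0]
    tot = out.allele_depths.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(tot > 0, ref / tot, np.nan)
    het = out.codes == 1
    bad = het & np.isfinite(ratio) & ((ratio < lo) | (ratio > hi))
    out.codes[bad] = MISSING
    return out


def _mac_per_locus(codes: np.ndarray) -> np.ndarray:
    called = codes != MISSING
    n2 = 2 * called.sum(axis=0)
    alt = np.where(called, codes, 0).sum(axis=0)
    return np.minimum(alt, n2 - alt)


def filter_loci(m: GenotypeMatrix, cfg: FilterConfig | None = None
                ) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the full cascade and drop failing loci.

    Returns the filtered matrix and a stage-by-stage report.  MAC is counted
    on post-masking calls; missingness is the per-locus missing fraction after
    all masking.  An empty result is allowed but logged loudly.
    """
    cfg = cfg or FilterConfig()
    report = FilterReport()
    n_loci0 = m.n_loci

    before = (m.codes != MISSING).sum()
    masked = mask_low_quality_calls(m, cfg)
    report.add("quality_mask", n_loci0, n_loci0,
               int(before - (masked.codes != MISSING).sum()))

    before = (masked.codes != MISSING).sum()
    balanced = filter_allele_balance(masked, cfg)
    report.add("allele_balance", n_loci0, n_loci0,
               int(before - (balanced.codes != MISSING).sum()))

    mac = _mac_per_locus(balanced.codes)
    keep_mac = mac >= cfg.min_mac
    report.add("min_mac", n_loci0, int(keep_mac.sum()))

    miss_frac = (balanced.codes == MISSING).mean(axis=0)
    keep_miss = keep_mac & (miss_frac <= cfg.max_locus_missing)
    report.add("missingness", int(keep_mac.sum()), int(keep_miss.sum()))

    out = balanced.subset(loci=[l for l, k in zip(balanced.locus_ids, keep_miss) if k])

    if cfg.max_sample_missing is not None:
        sample_miss = (out.codes == MISSING).mean(axis=1)
        keep_s = sample_miss <= cfg.max_sample_missing
        out = out.subset(samples=[s for s, k in zip(out.sample_ids, keep_s) if k])
        report.add("sample_missingness", out.n_loci, out.n_loci,
                   int((~keep_s).sum()))

    if out.n_loci == 0:
        logger.warning("filter cascade removed every locus")
    return out, report
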