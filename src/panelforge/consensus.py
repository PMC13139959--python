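"""Consensus genotypes and QC from repeated genotyping runs.

A sample is genotyped R times (typically in quadruplicate on a microfluidic
chip).  QC proceeds in a fixed order: replicates with a call rate <= 85% are
excluded; loci that amplified in fewer than 80% of all retained reactions are
removed; consensus genotypes are then built per sample and locus:

* two or more replicates missing at a locus  -> insufficient data (missing);
* otherwise the majority genotype wins (e.g. three consistent homozygotes
  beat one heterozygote);
* a 2-het vs 2-opposite-homozygote split is called heterozygous;
* other genotype-class ties fall back to the most prevalent allele, and an
  unresolvable 2-vs-2 opposite-homozygote split with no hets is missing.

Concordance is quantified per allele copy: the Match Score is the percentage
of allele copies agreeing between two replicate genotype vectors (a het/hom
mismatch costs half a genotype), and the genotyping error rate is exactly
100 - Match Score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, ReplicateSet

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusResult",
    "replicate_call_rates",
    "locus_success_filter",
    "build_consensus",
    "match_score",
    "pairwise_match_scores",
]


@dataclass
class ConsensusResult:
    consensus: GenotypeMatrix
    call_rates: pd.DataFrame  # sample, replicate, call_rate, excluded
    mean_call_rate: pd.Series  # per sample, over retained replicates
    agreement: pd.DataFrame  # sample x locus in {agree, disagree, insufficient}
    match_score: pd.Series  # per sample, %
    error_rate: pd.Series  # per sample, exactly 100 - match_score
    failed_samples: list[str] = field(default_factory=list)


def replicate_call_rates(rs: ReplicateSet, exclude_at_or_below: float = 85.0
                         ) -> pd.DataFrame:
    """Per-replicate call rates (%) with exclusion flags.

    Replicates at or below the threshold (default 85%) are flagged for
    exclusion before consensus building.
    """
    rates = 100.0 * (rs.codes != MISSING).mean(axis=2)  # (n, R)
    rows = []
    for i, s in enumerate(rs.sample_ids):
        for r in range(rs.n_replicates):
            rows.append(
                {
                    "sample": s,
                    "replicate": r,
                    "call_rate": rates[i, r],
                    "excluded": bool(rates[i, r] <= exclude_at_or_below),
                }
            )
    return pd.DataFrame(rows)


def locus_success_filter(rs: ReplicateSet, min_success: float = 0.8,
                         retained: pd.DataFrame | None = None
                         ) -> tuple[ReplicateSet, pd.DataFrame]:
    """Drop loci that amplified in < ``min_success`` of all reactions.

    The success fraction counts every (sample x retained replicate) reaction;
    exactly the threshold is retained ("less than 80% ... removed").
    ``retained`` may carry the call-rate table so excluded replicates do not
    count as reactions.
    """
    keep_rep = np.ones((rs.n_samples, rs.n_replicates), dtype=bool)
    if retained is not None:
        for row in retained.itertuples(index=False):
            if row.excluded:
                keep_rep[rs.sample_ids.index(row.sample), row.replicate] = False
    flat = rs.codes[keep_rep]  # (reactions, L)
    success = (flat != MISSING).mean(axis=0)
    keep = success >= min_success
    report = pd.DataFrame(
        {"locus_id": rs.locus_ids, "success_rate": success, "retained": keep}
    )
    kept = rs.subset_loci([l for l, k in zip(rs.locus_ids, keep) if k])
    return kept, report


def _consensus_call(calls: np.ndarray) -> tuple[int, str]:
    """Consensus genotype and agreement class for one sample x locus stack."""
    missing = int((calls == MISSING).sum())
    present = calls[calls != MISSING]
    if missing >= 2 or present.size == 0:
        return MISSING, "insufficient"
    values, counts = np.unique(present, return_counts=True)
    if values.size == 1:
        return int(values[0]), "agree"
    top = counts.max()
    winners = values[counts == top]
    if winners.size == 1:
        return int(winners[0]), "disagree"
    # genotype-class tie: fall back to the most prevalent allele
    alt_frac = present.sum() / (2.0 * present.size)
    if alt_frac < 0.5:
        return 0, "disagree"
    if alt_frac > 0.5:
        return 2, "disagree"
    if (present == 1).any():  # e.g. two hets vs two opposite homozygotes
        return 1, "disagree"
    return MISSING, "insufficient"  # 2 vs 2 opposite homozygotes, no hets


def match_score(v1: np.ndarray, v2: np.ndarray) -> float:
    """Percentage of allele copies matching between two genotype vectors.

    Loci missing in either vector are skipped; a het vs hom mismatch scores
    1 of 2 allele copies.  NaN when no locus is comparable.
    """
    v1 = np.asarray(v1)
    v2 = np.asarray(v2)
    ok = (v1 != MISSING) & (v2 != MISSING)
    if not ok.any():
        return float("nan")
    shared = 2.0 - np.abs(v1[ok].astype(float) - v2[ok].astype(float))
    return float(100.0 * shared.sum() / (2.0 * ok.sum()))


def pairwise_match_scores(vectors: np.ndarray) -> float:
    """Mean Match Score over all replicate pairs of one sample."""
    scores = [match_score(a, b) for a, b in combinations(vectors, 2)]
    scores = [s for s in scores if np.isfinite(s)]
    return float(np.mean(scores)) if scores else float("nan")


def build_consensus(rs: ReplicateSet, exclude_at_or_below: float = 85.0,
                    min_locus_success: float | None = 0.8) -> ConsensusResult:
    """Full QC + consensus pipeline for a replicate set.

    Order: replicate exclusion (call rate <= 85%) -> locus success filter
    (when ``min_locus_success`` is not None) -> per-locus consensus calls.
    Samples whose replicates are all excluded are flagged failed and emit
    all-missing consensus rows.
    """
    rates = replicate_call_rates(rs, exclude_at_or_below)
    if min_locus_success is not None:
        rs_kept, _ = locus_success_filter(rs, min_locus_success, retained=rates)
    else:
        rs_kept = rs

    n, L = rs_kept.n_samples, rs_kept.n_loci
    consensus = np.full((n, L), MISSING, dtype=np.int8)
    agreement = np.full((n, L), "insufficient", dtype=object)
    match = np.full(n, np.nan)
    mean_rate = np.full(n, np.nan)
    failed: list[str] = []

    for i, s in enumerate(rs_kept.sample_ids):
        rep_rows = rates[(rates["sample"] == s) & (~rates["excluded"])]
        reps = rep_rows["replicate"].to_numpy()
        if reps.size == 0:
            failed.append(s)
            continue
        mean_rate[i] = rep_rows["call_rate"].mean()
        stack = rs_kept.codes[i, reps, :]
        for j in range(L):
            consensus[i, j], agreement[i, j] = _consensus_call(stack[:, j])
        if reps.size >= 2:
            match[i] = pairwise_match_scores(stack)

    result_matrix = GenotypeMatrix(
        sample_ids=list(rs_kept.sample_ids),
        locus_ids=list(rs_kept.locus_ids),
        codes=consensus,
    )
    match_s = pd.Series(match, index=rs_kept.sample_ids, name="match_score")
    return ConsensusResult(
        consensus=result_matrix,
        call_rates=rates,
        mean_call_rate=pd.Series(mean_rate, index=rs_kept.sample_ids,
                                 name="mean_call_rate"),
        agreement=pd.DataFrame(agreement, index=rs_kept.sample_ids,
                               columns=rs_kept.locus_ids),
        match_score=match_s,
        error_rate=(100.0 - match_s).rename("error_rate"),
        failed_samples=failed,
    )
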