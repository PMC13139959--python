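"""Reduce a genome-wide SNP set to a small species-diagnostic panel.

The selection strategy mirrors how diagnostic assay panels are built from
RAD discovery data: take candidate subsets from windows of per-locus F_ST
(intermediate windows such as 0.3-0.5 usually separate recently diverged
species best), score each subset by how much variance PC1+PC2 capture and how
cleanly the known groups separate (silhouette in the PC1-PC2 plane), detect
loci that are strictly homozygous-diagnostic across all ascertainment
controls, enforce the assay-design spacing rule (no other SNP within 30 bp on
the same RAD locus, which would sit in a primer binding site), and assemble a
final fixed-size panel, optionally topped up with externally supplied loci
such as barcode SNPs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .core import MISSING, GenotypeMatrix, PopulationMap

logger = logging.getLogger(__name__)

__all__ = [
    "FstWindowSpec",
    "PanelSubset",
    "subset_by_fst_window",
    "score_subset",
    "pca_embedding",
    "find_diagnostic_snps",
    "apply_spacing_constraint",
    "assemble_panel",
]


@dataclass
class FstWindowSpec:
    """A closed per-locus theta window and how many loci to draw from it."""

    window: tuple[float, float] = (0.3, 0.5)
    subset_size: int = 200
    selection_rule: str = "random"  # or "midpoint": closest to window centre

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (0 <= lo < hi <= 1):
            raise ValueError("window must satisfy 0 <= low < high <= 1")
        if self.subset_size < 1:
            raise ValueError("subset_size must be >= 1")
        if self.selection_rule not in ("random", "midpoint"):
            raise ValueError("selection_rule must be 'random' or 'midpoint'")


@dataclass
class PanelSubset:
    locus_ids: list[str]
    window: tuple[float, float] | None = None
    pc12_variance: float | None = None  # % variance on PC1+PC2
    silhouette: float | None = None  # group separation in the PC1-PC2 plane
    distinct_clusters: bool | None = None


def subset_by_fst_window(stats: pd.DataFrame, spec: FstWindowSpec,
                         seed: int | None = None) -> PanelSubset:
    """Pick up to ``subset_size`` loci whose theta lies in the closed window.

    With more eligible loci than requested, the default rule draws a seeded
    uniform sample; the ``midpoint`` rule keeps those closest to the window
    centre.  Fewer eligible loci than requested are all returned with a
    warning; an empty window is also a warning, not an error.
    """
    if "theta" not in stats.columns:
        raise ValueError("per-locus theta required; run locus_summary with a popmap")
    lo, hi = spec.window
    theta = stats["theta"]
    eligible = stats.loc[theta.between(lo, hi, inclusive="both")]
    if eligible.empty:
        warnings.warn(f"no loci with theta in [{lo}, {hi}]")
        return PanelSubset(locus_ids=[], window=spec.window)
    if len(eligible) <= spec.subset_size:
        if len(eligible) < spec.subset_size:
            warnings.warn(
                f"only {len(eligible)} loci in window [{lo}, {hi}] "
                f"(requested {spec.subset_size})"
            )
        chosen = eligible["locus_id"].tolist()
    elif spec.selection_rule == "midpoint":
        mid = (lo + hi) / 2.0
        order = (eligible["theta"] - mid).abs().sort_values(kind="stable")
        chosen = eligible.loc[order.index[: spec.subset_size], "locus_id"].tolist()
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(eligible), size=spec.subset_size, replace=False)
        chosen = eligible.iloc[np.sort(idx)]["locus_id"].tolist()
    return PanelSubset(locus_ids=chosen, window=spec.window)


def pca_embedding(m: GenotypeMatrix, n_components: int = 2):
    """PCA on mean-imputed, column-centred genotype codes.

    Missing codes are replaced by the per-locus mean; no variance scaling is
    applied, so strongly differentiated (high-F_ST) loci keep their weight.
    Returns (coordinates, % variance per axis).
    """
    x = m.codes.astype(float)
    x[x == MISSING] = np.nan
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.nan_to_num(col_mean)  # all-missing column -> 0
    inds = np.where(np.isnan(x))
    x[inds] = col_mean[inds[1]]
    n_components = min(n_components, x.shape[0] - 1, x.shape[1])
    if n_components < 1:
        raise ValueError("not enough samples/loci for PCA")
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(x)
    return coords, 100.0 * pca.explained_variance_ratio_


def score_subset(m: GenotypeMatrix, subset: PanelSubset, popmap: PopulationMap,
                 silhouette_threshold: float = 0.5) -> PanelSubset:
    """Score a candidate subset by PC1+PC2 variance and group separation.

    "Distinct clusters" is operationalised as silhouette >= threshold on the
    known group labels in the PC1-PC2 plane (a quantitative stand-in for the
    visual three-clusters judgement panels are usually chosen by).
    """
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples to score a subset")
    sub = m.subset(loci=subset.locus_ids)
    coords, var = pca_embedding(sub, n_components=2)
    labels = np.array([popmap.group_of(s) for s in sub.sample_ids])
    if len(set(labels)) > 1 and all(
        np.sum(labels == g) >= 1 for g in set(labels)
    ) and coords.shape[0] > len(set(labels)):
        sil = float(silhouette_score(coords[:, :2], labels))
    else:
        sil = float("nan")
    return PanelSubset(
        locus_ids=list(subset.locus_ids),
        window=subset.window,
        pc12_variance=float(var[:2].sum()),
        silhouette=sil,
        distinct_clusters=bool(sil >= silhouette_threshold) if np.isfinite(sil) else False,
    )


def find_diagnostic_snps(m: GenotypeMatrix, popmap: PopulationMap) -> pd.DataFrame:
    """Loci that are strictly homozygous-diagnostic for one group.

    A locus is diagnostic for group S when every control of S is homozygous
    for one allele, every control of every other group is homozygous for the
    other allele, and no control call is missing.  Equivalent to brute-force
    per-locus enumeration.
    """
    controls = popmap.controls_by_group()
    if not controls:
        raise ValueError("no control samples labelled in the population map")
    present = set(m.sample_ids)
    blocks = {g: m.codes[m.sample_index([s for s in ids if s in present])]
              for g, ids in controls.items()}
    blocks = {g: b for g, b in blocks.items() if b.shape[0] > 0}
    rows = []
    for j, locus in enumerate(m.locus_ids):
        calls = {g: b[:, j] for g, b in blocks.items()}
        if any((c == MISSING).any() for c in calls.values()):
            continue
        fixed = {}
        for g, c in calls.items():
            if np.all(c == 0):
                fixed[g] = 0
            elif np.all(c == 2):
                fixed[g] = 2
            else:
                fixed[g] = None
        if any(v is None for v in fixed.values()):
            continue
        for g, allele in fixed.items():
            others = [fixed[h] for h in fixed if h != g]
            if others and all(o == 2 - allele for o in others):
                rows.append({"locus_id": locus, "species": g})
                break
    return pd.DataFrame(rows, columns=["locus_id", "species"])


def apply_spacing_constraint(candidates: list[str], loci: pd.DataFrame,
                             min_gap: int = 30) -> list[str]:
    """Drop candidates with any other SNP within ``min_gap`` bp on their locus.

    ``loci`` is per-SNP metadata (indexed by SNP id) with ``contig`` and
    ``position_in_locus`` columns covering *all* known SNPs, not just the
    candidates: a non-candidate neighbour also spoils a primer site.
    Candidates with no position metadata are kept with a warning.
    """
    if not {"contig", "position_in_locus"}.issubset(loci.columns):
        warnings.warn("no contig/position metadata; spacing rule skipped")
        return list(candidates)
    out = []
    for snp in candidates:
        if snp not in loci.index or pd.isna(loci.loc[snp, "position_in_locus"]):
            warnings.warn(f"{snp}: no position; kept without spacing check")
            out.append(snp)
            continue
        contig = loci.loc[snp, "contig"]
        pos = loci.loc[snp, "position_in_locus"]
        same = loci[(loci["contig"] == contig) & (loci.index != snp)]
        gaps = (same["position_in_locus"] - pos).abs()
        if (gaps <= min_gap).any():
            continue
        out.append(snp)
    return out


def assemble_panel(
    scored_subsets: list[PanelSubset],
    m: GenotypeMatrix,
    popmap: PopulationMap,
    target_size: int = 19,
    diagnostic: pd.DataFrame | None = None,
    extra_loci: list[str] | None = None,
    stats: pd.DataFrame | None = None,
    silhouette_threshold: float = 0.5,
) -> PanelSubset:
    """Assemble the final panel from the best-scoring window subset.

    Subsets are ranked by (distinct-cluster flag, PC1+PC2 variance).  Within
    the winning subset, diagnostic loci are taken first, then the remainder by
    descending theta (or input order when no stats are given), up to
    ``target_size``; user-supplied extra loci (e.g. barcode SNPs) are appended
    and de-duplicated.  The result is re-scored so the distinct-cluster
    criterion can be checked on the panel itself.
    """
    ranked = sorted(
        (s for s in scored_subsets if s.locus_ids),
        key=lambda s: (bool(s.distinct_clusters), s.pc12_variance or 0.0),
        reverse=True,
    )
    if not ranked:
        raise ValueError("no non-empty scored subsets to assemble from")
    # a subset too small to fill the panel only wins if no other can
    full = [s for s in ranked if len(s.locus_ids) >= target_size]
    best = full[0] if full else ranked[0]
    if target_size > len(best.locus_ids):
        raise ValueError(
            f"target_size {target_size} exceeds the {len(best.locus_ids)} "
            "loci available in the best subset"
        )
    diag = set() if diagnostic is None else set(diagnostic["locus_id"])
    if stats is not None and "theta" in stats.columns:
        theta = stats.set_index("locus_id")["theta"]
        order = sorted(
            best.locus_ids,
            key=lambda l: (l not in diag, -float(theta.get(l, float("-inf")))),
        )
    else:
        order = sorted(best.locus_ids, key=lambda l: l not in diag)
    chosen = order[:target_size]
    for extra in extra_loci or []:
        if extra not in chosen:
            chosen.append(extra)
    panel = PanelSubset(locus_ids=chosen, window=best.window)
    panel = score_subset(m, panel, popmap, silhouette_threshold)
    if not panel.distinct_clusters:
        logger.warning("assembled panel does not meet the distinct-cluster criterion")
    return panel
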