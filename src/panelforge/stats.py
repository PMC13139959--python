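"""Per-locus diversity statistics and population differentiation.

Implements the standard biallelic summaries used when characterising a SNP
panel — observed heterozygosity ``H_O``, Nei's unbiased gene diversity
``H_S = (2N/(2N-1)) (1 - p^2 - q^2)`` and Botstein's polymorphic information
content ``PIC = 1 - p^2 - q^2 - 2 p^2 q^2`` — together with the Weir &
Cockerham (1984) F_ST estimator ``theta = a / (a + b + c)`` from the among-
population (a), among-individual (b) and within-individual (c) variance
components, per locus and multilocus, with a percentile bootstrap over loci
for pairwise confidence intervals.

Missing data is handled pairwise-complete per locus: N varies by locus, as it
does in real panel summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "locus_summary",
    "group_frequencies",
    "wc_components",
    "wc_theta_per_locus",
    "pairwise_wc_fst",
    "PairwiseFst",
    "nei_da_distance",
    "nei_identity",
]


def _counts_per_locus(codes: np.ndarray):
    """(N, alt allele count, het count) per locus, ignoring missing calls."""
    called = codes != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, codes, 0).sum(axis=0)
    het = ((codes == 1) & called).sum(axis=0)
    return n, alt, het


def locus_summary(m: GenotypeMatrix, popmap: PopulationMap | None = None) -> pd.DataFrame:
    """Per-locus N, MAF, H_O, H_S and PIC (plus theta when a popmap is given).

    A monomorphic locus has H_S = PIC = 0; a locus with no calls gets NaN
    statistics.  MAF always refers to the rarer allele, independent of which
    allele the codes count.
    """
    n, alt, het = _counts_per_locus(m.codes)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = np.where(n > 0, alt / (2.0 * n), np.nan)
        maf = np.minimum(p_alt, 1.0 - p_alt)
        p, q = maf, 1.0 - maf
        ho = np.where(n > 0, het / n, np.nan)
        gene_div = 1.0 - p**2 - q**2
        hs = np.where(n > 0, (2.0 * n) / (2.0 * n - 1.0) * gene_div, np.nan)
        pic = 1.0 - p**2 - q**2 - 2.0 * p**2 * q**2
        pic = np.where(n > 0, pic, np.nan)
    out = pd.DataFrame(
        {
            "locus_id": m.locus_ids,
            "N": n,
            "MAF": maf,
            "H_O": ho,
            "H_S": hs,
            "PIC": pic,
        }
    )
    if popmap is not None:
        out["theta"] = wc_theta_per_locus(m, popmap)
    return out


def _group_blocks(m: GenotypeMatrix, popmap: PopulationMap,
                  groups: list[str] | None = None):
    """Code blocks per group, restricted to samples present in the matrix."""
    present = set(m.sample_ids)
    groups = groups or popmap.groups()
    blocks = []
    for g in groups:
        ids = [s for s in popmap.samples_in_group(g) if s in present]
        if ids:
            blocks.append((g, m.codes[m.sample_index(ids)]))
    return blocks


def group_frequencies(m: GenotypeMatrix, popmap: PopulationMap,
                      groups: list[str] | None = None) -> pd.DataFrame:
    """Alternate-allele frequency per group (rows) and locus (columns)."""
    rows, index = [], []
    for g, codes in _group_blocks(m, popmap, groups):
        n, alt, _ = _counts_per_locus(codes)
        with np.errstate(divide="ignore", invalid="ignore"):
            rows.append(np.where(n > 0, alt / (2.0 * n), np.nan))
        index.append(g)
    if not rows:
        raise ValueError("no mapped samples found in the matrix")
    return pd.DataFrame(rows, index=index, columns=m.locus_ids)


def wc_components(m: GenotypeMatrix, popmap: PopulationMap,
                  groups: list[str] | None = None):
    """Weir-Cockerham (1984) variance components (a, b, c) per locus.

    Computed from per-population sample sizes n_i, alternate-allele
    frequencies p_i and observed heterozygote frequencies h_i:

        n_bar = mean n_i                        (weighted means throughout)
        n_c   = (r n_bar - sum n_i^2 / (r n_bar)) / (r - 1)
        s^2   = sum n_i (p_i - p_bar)^2 / ((r - 1) n_bar)

        a = (n_bar/n_c) [ s^2 - (p_bar(1-p_bar) - (r-1)/r s^2 - h_bar/4)/(n_bar-1) ]
        b = n_bar/(n_bar-1) [ p_bar(1-p_bar) - (r-1)/r s^2 - (2 n_bar - 1)/(4 n_bar) h_bar ]
        c = h_bar / 2

    Loci where fewer than two groups have data, or where n_bar <= 1, get NaN
    components.
    """
    blocks = _group_blocks(m, popmap, groups)
    if len(blocks) < 2:
        raise ValueError("Weir-Cockerham theta needs at least two groups")
    L = m.n_loci
    ns, ps, hs = [], [], []
    for _, codes in blocks:
        n, alt, het = _counts_per_locus(codes)
        with np.errstate(divide="ignore", invalid="ignore"):
            ps.append(np.where(n > 0, alt / (2.0 * n), np.nan))
            hs.append(np.where(n > 0, het / n, np.nan))
        ns.append(n.astype(float))
    n_i = np.array(ns)  # (r, L)
    p_i = np.array(ps)
    h_i = np.array(hs)

    has = n_i > 0
    r = has.sum(axis=0).astype(float)  # populations with data, per locus
    n_i = np.where(has, n_i, 0.0)
    p_i = np.where(has, p_i, 0.0)
    h_i = np.where(has, h_i, 0.0)

    n_tot = n_i.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        n_bar = n_tot / r
        n_c = (n_tot - (n_i**2).sum(axis=0) / n_tot) / (r - 1.0)
        p_bar = (n_i * p_i).sum(axis=0) / n_tot
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1.0) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / n_tot

        pq = p_bar * (1.0 - p_bar)
        a = (n_bar / n_c) * (
            s2 - (pq - (r - 1.0) / r * s2 - h_bar / 4.0) / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            pq - (r - 1.0) / r * s2 - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
        )
        c = h_bar / 2.0

    bad = (r < 2) | (n_bar <= 1.0) | ~np.isfinite(n_c) | (n_c <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def wc_theta_per_locus(m: GenotypeMatrix, popmap: PopulationMap,
                       groups: list[str] | None = None) -> np.ndarray:
    """Per-locus theta = a/(a+b+c); NaN where undefined (a+b+c = 0)."""
    a, b, c = wc_components(m, popmap, groups)
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(np.isclose(denom, 0.0), np.nan, a / denom)
    return theta


@dataclass
class PairwiseFst:
    group_a: str
    group_b: str
    theta: float
    ci_low: float
    ci_high: float
    n_boot: int
    significant: bool  # 95% CI excludes zero


def multilocus_theta(m: GenotypeMatrix, popmap: PopulationMap,
                     groups: list[str] | None = None) -> float:
    """Ratio-of-sums multilocus theta = sum a / sum (a+b+c) over loci."""
    a, b, c = wc_components(m, popmap, groups)
    denom = a + b + c
    ok = np.isfinite(denom) & ~np.isclose(denom, 0.0)
    if not ok.any():
        return float("nan")
    return float(a[ok].sum() / denom[ok].sum())


def pairwise_wc_fst(m: GenotypeMatrix, popmap: PopulationMap,
                    n_boot: int = 1000, seed: int | None = None,
                    alpha: float = 0.05) -> list[PairwiseFst]:
    """Pairwise multilocus theta with percentile bootstrap CIs over loci.

    The CI resamples loci with replacement ``n_boot`` times and takes the
    (alpha/2, 1-alpha/2) percentiles of the ratio-of-sums theta; the pair is
    flagged significant when the CI excludes zero.
    """
    if m.n_loci < 2:
        raise ValueError("pairwise F_ST needs at least two loci")
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    results = []
    for g1, g2 in combinations(popmap.groups(), 2):
        a, b, c = wc_components(m, popmap, groups=[g1, g2])
        denom = a + b + c
        ok = np.isfinite(denom) & ~np.isclose(denom, 0.0)
        a, denom = a[ok], denom[ok]
        if a.size == 0:
            results.append(PairwiseFst(g1, g2, float("nan"), float("nan"),
                                       float("nan"), n_boot, False))
            continue
        theta = float(a.sum() / denom.sum())
        idx = rng.integers(0, a.size, size=(n_boot, a.size))
        boot = a[idx].sum(axis=1) / denom[idx].sum(axis=1)
        lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        results.append(PairwiseFst(g1, g2, theta, float(lo), float(hi),
                                   n_boot, bool(lo > 0 or hi < 0)))
    return results


def _check_shared(x: pd.DataFrame) -> pd.DataFrame:
    shared = x.dropna(axis=1, how="any")
    if shared.shape[1] == 0:
        raise ValueError("no shared loci across groups")
    return shared


def nei_da_distance(freqs: pd.DataFrame) -> pd.DataFrame:
    """Nei's D_A distance between groups from biallelic frequencies.

    ``freqs`` is groups x loci (alternate-allele frequency).  For each pair,
    D_A = 1 - (1/L) sum_l [ sqrt(x_l y_l) + sqrt((1-x_l)(1-y_l)) ].
    """
    f = _check_shared(freqs)
    groups = list(f.index)
    x = f.to_numpy()
    d = np.zeros((len(groups), len(groups)))
    for i, j in combinations(range(len(groups)), 2):
        sim = np.sqrt(x[i] * x[j]) + np.sqrt((1 - x[i]) * (1 - x[j]))
        d[i, j] = d[j, i] = 1.0 - sim.mean()
    return pd.DataFrame(d, index=groups, columns=groups)


def nei_identity(freqs: pd.DataFrame) -> pd.DataFrame:
    """Nei's genetic identity I between groups (normalised gene identity).

    I = j_xy / sqrt(j_x j_y) with j summed over loci and both alleles;
    I(self) = 1, and fully fixed opposite groups give I = 0.
    """
    f = _check_shared(freqs)
    groups = list(f.index)
    x = f.to_numpy()
    n = len(groups)
    ident = np.eye(n)
    selfsums = [(x[i] ** 2 + (1 - x[i]) ** 2).sum() for i in range(n)]
    if any(np.isclose(s, 0) for s in selfsums):  # cannot happen for p in [0,1]
        raise ValueError("degenerate zero-variance frequency input")
    for i, j in combinations(range(n), 2):
        jxy = (x[i] * x[j] + (1 - x[i]) * (1 - x[j])).sum()
        ident[i, j] = ident[j, i] = jxy / np.sqrt(selfsums[i] * selfsums[j])
    return pd.DataFrame(ident, index=groups, columns=groups)
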