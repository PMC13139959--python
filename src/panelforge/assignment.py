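"""Species assignment and clustering from small SNP panels.

The primary assignment rule is allele sharing: between two diploid genotypes
the similarity at a locus is the fraction of allele copies shared (0, 0.5 or
1), the allele-sharing distance (ASD) is one minus its mean over loci typed in
both samples, and a sample's "shared genotypic information" with a reference
group is the mean allele-sharing similarity with that group's control plants.
A sample is assigned to the top group when its sharing reaches the threshold
(default 80%); otherwise it is reported unassigned with its two top sharing
fractions — the signature of an admixed or intermediate individual.

Corroborating analyses: UPGMA (average linkage, lexicographic tie-break) with
locus-resampled bootstrap supports; classical PCoA / PCA; an ADMIXTURE-style
binomial-mixture EM over ancestry fractions Q and cluster frequencies F with
masked-entry cross-validation for choosing K; multilocus genotype matching;
and frequency-based (HWE likelihood) assignment tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .core import MISSING, GenotypeMatrix, PopulationMap
from .panel import pca_embedding

logger = logging.getLogger(__name__)

__all__ = [
    "allele_sharing_distance",
    "AssignmentResult",
    "assign_by_sharing",
    "UpgmaNode",
    "upgma_tree",
    "upgma_with_support",
    "pcoa",
    "pca",
    "AncestryEstimate",
    "admixture_em",
    "select_k",
    "multilocus_matches",
    "frequency_assignment_test",
]


# ---------------------------------------------------------------------------
# Allele sharing
# ---------------------------------------------------------------------------

def allele_sharing_distance(m: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise allele-sharing distance matrix (Bowcock).

    Per pair and locus, similarity = (shared allele copies)/2, i.e.
    ``1 - |g_i - g_j|/2`` on dosage codes; the distance is one minus the mean
    over loci non-missing in both samples.  A pair with no shared typed locus
    gets NaN and a warning.
    """
    if m.n_samples < 2:
        raise ValueError("need at least two samples")
    g = m.codes.astype(float)
    g[m.codes == MISSING] = np.nan
    n = m.n_samples
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        diff = np.abs(g[i] - g[j])
        ok = ~np.isnan(diff)
        if not ok.any():
            warnings.warn(
                f"samples {m.sample_ids[i]!r}, {m.sample_ids[j]!r} share no typed loci"
            )
            d[i, j] = d[j, i] = np.nan
            continue
        d[i, j] = d[j, i] = np.mean(diff[ok]) / 2.0
    return pd.DataFrame(d, index=m.sample_ids, columns=m.sample_ids)


@dataclass
class AssignmentResult:
    sample_id: str
    shared: dict[str, float]  # group -> % genotypic information shared
    assigned: str | None  # None == unassigned / admixed
    top_two: tuple[tuple[str, float], tuple[str, float]] | None = None


def assign_by_sharing(m: GenotypeMatrix, popmap: PopulationMap,
                      threshold: float = 0.80,
                      aggregate: str = "mean") -> list[AssignmentResult]:
    """Assign unknowns to the control group they share the most alleles with.

    Sharing with a group is the mean (or max, configurable) allele-sharing
    similarity over the group's controls, in percent.  A sample is assigned to
    the argmax group only when that sharing is >= 100*threshold; otherwise it
    is left unassigned and its two top fractions are reported.
    """
    controls = popmap.controls_by_group()
    if not controls:
        raise ValueError("no control samples available for assignment")
    if aggregate not in ("mean", "max"):
        raise ValueError("aggregate must be 'mean' or 'max'")
    d = allele_sharing_distance(m)
    unknowns = [s for s in m.sample_ids
                if s in set(popmap.table.loc[popmap.table["role"] == "unknown",
                                             "sample"])]
    present = set(m.sample_ids)
    results = []
    for s in unknowns:
        shared = {}
        for g, ctrl in controls.items():
            ctrl = [c for c in ctrl if c in present and c != s]
            if not ctrl:
                continue
            sims = 100.0 * (1.0 - d.loc[s, ctrl].to_numpy(dtype=float))
            shared[g] = float(np.nanmax(sims) if aggregate == "max"
                              else np.nanmean(sims))
        ranked = sorted(shared.items(), key=lambda kv: kv[1], reverse=True)
        best_group, best_share = ranked[0]
        if best_share >= 100.0 * threshold:
            results.append(AssignmentResult(s, shared, best_group))
        else:
            top_two = (ranked[0], ranked[1]) if len(ranked) > 1 else (ranked[0],) * 2
            results.append(AssignmentResult(s, shared, None, top_two))
    return results


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class UpgmaNode:
    """Binary ultrametric tree node; leaves carry a name, internals a height."""

    name: str | None = None
    height: float = 0.0
    children: list["UpgmaNode"] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def bipartitions(self) -> list[frozenset[str]]:
        """Leaf sets of every internal node (including the root)."""
        out = []
        if self.children:
            out.append(frozenset(self.leaves()))
            for c in self.children:
                out.extend(c.bipartitions())
        return out

    def _internal_nodes(self):
        if self.children:
            yield self
            for c in self.children:
                yield from c._internal_nodes()

    def to_newick(self, with_support: bool = False) -> str:
        def fmt(node: UpgmaNode, parent_height: float) -> str:
            blen = parent_height - node.height
            if not node.children:
                return f"{node.name}:{blen:.6g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:.2f}"
            return f"({inner}){label}:{blen:.6g}"

        inner = ",".join(fmt(c, self.height) for c in self.children)
        label = f"{self.support:.2f}" if (with_support and self.support is not None) else ""
        return f"({inner}){label};"


def upgma_tree(d: pd.DataFrame | np.ndarray,
               labels: list[str] | None = None) -> UpgmaNode:
    """Average-linkage (UPGMA) agglomeration with ultrametric node heights.

    Cluster distance is the size-weighted average of member distances; the
    merge height is half the joining distance.  Ties are broken by merging the
    lexicographically smallest eligible pair of cluster label tuples, so the
    tree is deterministic.
    """
    if isinstance(d, pd.DataFrame):
        labels = list(d.index)
        dist = d.to_numpy(dtype=float)
    else:
        dist = np.asarray(d, dtype=float)
        labels = labels or [f"s{i}" for i in range(dist.shape[0])]
    if dist.shape[0] != dist.shape[1] or not np.allclose(dist, dist.T, equal_nan=True):
        raise ValueError("distance matrix must be square and symmetric")
    if np.isnan(dist).any():
        raise ValueError("distance matrix contains missing entries")

    clusters: dict[int, UpgmaNode] = {
        i: UpgmaNode(name=labels[i]) for i in range(len(labels))
    }
    sizes = {i: 1 for i in clusters}
    keys = {i: (labels[i],) for i in clusters}  # sorted leaf tuple, for tie-break
    dmat = {(i, j): dist[i, j] for i, j in combinations(range(len(labels)), 2)}
    next_id = len(labels)

    while len(clusters) > 1:
        best = min(
            dmat.items(),
            key=lambda kv: (kv[1], tuple(sorted((keys[kv[0][0]], keys[kv[0][1]])))),
        )
        (i, j), dij = best
        node = UpgmaNode(height=dij / 2.0, children=[clusters[i], clusters[j]])
        clusters.pop(i), clusters.pop(j)
        new_dists = {}
        for k in clusters:
            a, b = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            new_dists[k] = (sizes[i] * dmat[a] + sizes[j] * dmat[b]) / (sizes[i] + sizes[j])
        dmat = {(a, b): v for (a, b), v in dmat.items()
                if i not in (a, b) and j not in (a, b)}
        clusters[next_id] = node
        sizes[next_id] = sizes.pop(i) + sizes.pop(j)
        keys[next_id] = tuple(sorted(keys.pop(i) + keys.pop(j)))
        for k, v in new_dists.items():
            dmat[(min(k, next_id), max(k, next_id))] = v
        next_id += 1
    return next(iter(clusters.values()))


def upgma_with_support(m: GenotypeMatrix, n_boot: int = 100,
                       seed: int | None = None) -> UpgmaNode:
    """UPGMA on the allele-sharing distance with locus-resampled supports.

    Each bootstrap replicate resamples loci with replacement, recomputes the
    ASD and the UPGMA tree, and each original internal node's support is the
    fraction of replicate trees containing its leaf bipartition.
    """
    d = allele_sharing_distance(m)
    tree = upgma_tree(d)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
        for _ in range(n_boot):
            idx = rng.integers(0, m.n_loci, size=m.n_loci)
            mb = GenotypeMatrix(
                sample_ids=list(m.sample_ids),
                locus_ids=[f"b{i}" for i in range(m.n_loci)],
                codes=m.codes[:, idx],
            )
            boot_bps = set(upgma_tree(allele_sharing_distance(mb)).bipartitions())
            for bp in counts:
                if bp in boot_bps:
                    counts[bp] += 1
        for node in tree._internal_nodes():
            node.support = counts[frozenset(node.leaves())] / n_boot
    return tree


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

def pcoa(d: pd.DataFrame):
    """Classical PCoA (metric MDS) on a distance matrix.

    Returns (coordinates DataFrame, % variance per retained axis).  Axes with
    negative eigenvalues are dropped with a note, as usual for non-Euclidean
    distances.
    """
    dm = DistanceMatrix(d.to_numpy(dtype=float), ids=[str(i) for i in d.index])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        res = _skbio_pcoa(dm, method="eigh")
    eig = res.eigvals.to_numpy()
    keep = eig > 1e-12
    if (~keep).any() and (eig < -1e-9).any():
        logger.info("dropped %d negative-eigenvalue axes", int((eig < 0).sum()))
    coords = res.samples.iloc[:, : keep.sum()]
    var = 100.0 * res.proportion_explained.to_numpy()[: keep.sum()]
    coords.index = d.index
    return coords, var


def pca(m: GenotypeMatrix, n_components: int = 2):
    """Genotype PCA (mean-imputed, centred); same contract as pcoa."""
    coords, var = pca_embedding(m, n_components=n_components)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=m.sample_ids, columns=cols), var


# ---------------------------------------------------------------------------
# Admixture EM
# ---------------------------------------------------------------------------

@dataclass
class AncestryEstimate:
    Q: pd.DataFrame  # samples x K ancestry fractions, rows on the simplex
    F: pd.DataFrame  # K x loci cluster allele frequencies
    log_likelihood: float
    loglik_path: np.ndarray
    converged: bool
    admixed: pd.Series  # True when max_k q_ik < 0.8


_EPS = 1e-9


def _em_loglik(g, mask, Q, F):
    p = Q @ F
    p = np.clip(p, _EPS, 1 - _EPS)
    ll = np.where(mask, g * np.log(p) + (2 - g) * np.log(1 - p), 0.0)
    return float(ll.sum())


def admixture_em(m: GenotypeMatrix, K: int, seed: int | None = None,
                 max_iter: int = 500, tol: float = 1e-4,
                 admixture_cutoff: float = 0.8,
                 warn_nonconvergence: bool = True) -> AncestryEstimate:
    """Maximum-likelihood ancestry fractions via EM on a binomial mixture.

    Model: dosage g_il ~ Binomial(2, sum_k q_ik f_kl) with each of the two
    allele copies drawn from cluster k with probability q_ik.  The EM block
    updates are the classical frappe/ADMIXTURE updates; the log-likelihood is
    non-decreasing every iteration, and missing genotypes simply drop out of
    the likelihood.  K = 1 reduces to observed frequencies in closed form.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    g = m.codes.astype(float)
    mask = m.codes != MISSING
    g[~mask] = 0.0
    n, L = g.shape
    gm = np.where(mask, g, 0.0)
    cm = np.where(mask, 2.0 - g, 0.0)

    rng = np.random.default_rng(seed)
    Q = rng.dirichlet(np.ones(K), size=n)
    with np.errstate(invalid="ignore"):
        base = gm.sum(axis=0) / np.maximum((2.0 * mask.sum(axis=0)), 1.0)
    F = np.clip(base + 0.1 * rng.standard_normal((K, L)), 0.01, 0.99)
    if K == 1:
        Q = np.ones((n, 1))
        F = base[None, :]

    path = []
    prev = -np.inf
    converged = False
    for it in range(max_iter):
        P = np.clip(Q @ F, _EPS, 1 - _EPS)  # (n, L)
        # responsibilities split by allele type: expected alt / ref copies from k
        QF = Q[:, :, None] * F[None, :, :]  # (n, K, L)
        Qf = Q[:, :, None] * (1.0 - F)[None, :, :]
        alt_resp = QF / P[:, None, :]
        ref_resp = Qf / (1.0 - P)[:, None, :]
        alt_k = alt_resp * gm[:, None, :]
        ref_k = ref_resp * cm[:, None, :]
        if K > 1:
            Q = (alt_k + ref_k).sum(axis=2)
            Q /= np.maximum(Q.sum(axis=1, keepdims=True), _EPS)
        denom = (alt_k + ref_k).sum(axis=0)
        F = np.where(denom > 0, alt_k.sum(axis=0) / np.maximum(denom, _EPS), F)
        F = np.clip(F, _EPS, 1 - _EPS)
        ll = _em_loglik(g, mask, Q, F)
        path.append(ll)
        if ll - prev < tol and it > 0:
            converged = True
            break
        prev = ll
    if not converged and warn_nonconvergence:
        logger.warning("admixture EM did not converge in %d iterations", max_iter)

    Qdf = pd.DataFrame(Q, index=m.sample_ids,
                       columns=[f"K{k + 1}" for k in range(K)])
    Fdf = pd.DataFrame(F, index=[f"K{k + 1}" for k in range(K)],
                       columns=m.locus_ids)
    admixed = pd.Series(Q.max(axis=1) < admixture_cutoff, index=m.sample_ids)
    return AncestryEstimate(Qdf, Fdf, path[-1], np.array(path), converged, admixed)


def select_k(m: GenotypeMatrix, k_range=range(1, 7), cv_fraction: float = 0.2,
             replicates: int = 5, seed: int | None = None,
             max_iter: int = 200, tol: float = 1e-2):
    """Choose K by masked-entry cross-validation.

    Per replicate, ``cv_fraction`` of the non-missing genotype entries are
    masked, the model is fit on the rest, and the masked dosages are predicted
    by their expectation 2 * sum_k q_ik f_kl; the CV error is the mean squared
    prediction error.  The best K minimises the mean CV error over replicates.

    Returns (best_k, curve) where ``curve`` is a DataFrame with one row per K.
    """
    rng = np.random.default_rng(seed)
    obs_idx = np.argwhere(m.codes != MISSING)
    if obs_idx.shape[0] < 10:
        raise ValueError("not enough non-missing genotypes for cross-validation")
    n_mask = max(1, int(round(cv_fraction * obs_idx.shape[0])))
    rows = []
    for k in k_range:
        errors = []
        for rep in range(replicates):
            pick = rng.choice(obs_idx.shape[0], size=n_mask, replace=False)
            masked = obs_idx[pick]
            codes = m.codes.copy()
            truth = codes[masked[:, 0], masked[:, 1]].astype(float)
            codes[masked[:, 0], masked[:, 1]] = MISSING
            mm = GenotypeMatrix(sample_ids=list(m.sample_ids),
                                locus_ids=list(m.locus_ids), codes=codes)
            try:
                # CV fits only need a stable plateau, not full convergence
                est = admixture_em(mm, k, seed=int(rng.integers(2**31)),
                                   max_iter=max_iter, tol=tol,
                                   warn_nonconvergence=False)
            except Exception:  # degenerate mask
                logger.warning("replicate %d at K=%d skipped", rep, k)
                continue
            pred = 2.0 * (est.Q.to_numpy() @ est.F.to_numpy())
            pred = pred[masked[:, 0], masked[:, 1]]
            errors.append(float(np.mean((pred - truth) ** 2)))
        rows.append({"K": k, "cv_error": float(np.mean(errors)),
                     "cv_sd": float(np.std(errors)), "n_replicates": len(errors)})
    curve = pd.DataFrame(rows)
    best_k = int(curve.loc[curve["cv_error"].idxmin(), "K"])
    return best_k, curve


# ---------------------------------------------------------------------------
# Multilocus genotypes & frequency-based assignment
# ---------------------------------------------------------------------------

def multilocus_matches(m: GenotypeMatrix, missing_wildcard: bool = False):
    """Group samples with identical multilocus genotypes (MLGs).

    Exact mode (default) requires identical vectors including missingness;
    wildcard mode lets a missing call match anything (transitively greedy).
    Returns (number of unique MLGs, list of match groups of size >= 2).
    """
    if missing_wildcard:
        groups: list[list[int]] = []
        for i in range(m.n_samples):
            placed = False
            for grp in groups:
                j = grp[0]
                a, b = m.codes[i], m.codes[j]
                ok = (a == MISSING) | (b == MISSING) | (a == b)
                if ok.all():
                    grp.append(i)
                    placed = True
                    break
            if not placed:
                groups.append([i])
    else:
        seen: dict[bytes, list[int]] = {}
        for i in range(m.n_samples):
            seen.setdefault(m.codes[i].tobytes(), []).append(i)
        groups = list(seen.values())
    match_groups = [[m.sample_ids[i] for i in g] for g in groups if len(g) > 1]
    return len(groups), match_groups


def frequency_assignment_test(m: GenotypeMatrix, popmap: PopulationMap,
                              ) -> pd.DataFrame:
    """HWE log-likelihood assignment of every sample to each control group.

    Group allele frequencies are estimated from controls; when scoring a
    control its own alleles are left out (leave-one-out).  Zero or one
    frequencies are floored/capped at 1/(2 N_G + 1).  Returns a frame with
    one log-likelihood column per group plus the argmax assignment (ties
    flagged).
    """
    controls = popmap.controls_by_group()
    if not controls:
        raise ValueError("no control groups with samples")
    present = set(m.sample_ids)
    idx = {g: m.sample_index([s for s in ids if s in present])
           for g, ids in controls.items()}
    rows = []
    for i, s in enumerate(m.sample_ids):
        logliks = {}
        for g, gi in idx.items():
            gi_eff = gi[gi != i]  # leave-one-out for the sample's own group
            if gi_eff.size == 0:
                continue
            codes = m.codes[gi_eff]
            called = codes != MISSING
            n2 = 2.0 * called.sum(axis=0)
            alt = np.where(called, codes, 0).sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(n2 > 0, alt / n2, np.nan)
            floor = 1.0 / (n2 + 1.0)
            p = np.clip(p, floor, 1.0 - floor)
            gcode = m.codes[i].astype(float)
            ok = (m.codes[i] != MISSING) & np.isfinite(p)
            pg, go = p[ok], gcode[ok]
            ll = go * np.log(pg) + (2 - go) * np.log(1 - pg)
            ll += np.where(go == 1, np.log(2.0), 0.0)  # HWE het multiplicity
            logliks[g] = float(ll.sum())
        ranked = sorted(logliks.items(), key=lambda kv: kv[1], reverse=True)
        tie = len(ranked) > 1 and np.isclose(ranked[0][1], ranked[1][1])
        rows.append({"sample": s, **{f"loglik_{g}": v for g, v in logliks.items()},
                     "assigned": ranked[0][0] if ranked else None, "tie": tie})
    return pd.DataFrame(rows)
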