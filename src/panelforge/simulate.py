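"""Synthetic genotype data with the statistical structure the pipeline assumes.

The generator emulates the study design this package targets: a small complex
of K diverged populations (default three), genome-wide biallelic SNPs whose
per-locus divergence is controlled by a Balding-Nichols model, uniform at
random missingness at the ~2% level, repeated genotyping runs (default four
per sample) with per-allele call errors, and optionally admixed individuals
with specified ancestry fractions.

The Balding-Nichols model draws, for each locus with ancestral frequency
``p`` and divergence parameter ``F`` in [0, 1), an independent population
frequency from ``Beta(p(1-F)/F, (1-p)(1-F)/F)``.  The expectation of the
resulting Weir-Cockerham F_ST over many loci matches the generating ``F``,
which is what makes the parameter a direct dial for per-locus F_ST and the
reason this model was chosen for a panel-design test bed.

All randomness flows from one integer seed through named substreams, so every
output is bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PopulationMap, ReplicateSet

__all__ = [
    "SimulationConfig",
    "FrequencyTable",
    "ReplicateSpec",
    "simulate_frequencies",
    "simulate_genotypes",
    "simulate_admixed",
    "simulate_replicates",
    "simulate_study",
]


def _substream(seed: int | None, label: str) -> np.random.Generator:
    """Derive a named, reproducible substream from one global seed.

    Uses a CRC of the label (not ``hash``, which is per-process salted) so the
    same seed always yields the same stream for each stage.
    """
    if seed is None:
        return np.random.default_rng()
    child = np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    return np.random.default_rng(child)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults are the desk-scale conditions the pipeline is exercised under:
    three populations, 2000 discovery loci, per-locus divergence F drawn
    uniformly from [0.2, 0.7), ancestral minor-allele frequencies uniform in
    [0.05, 0.5], sample sizes 20/20/10 and a 2% missing-call rate (the ~98%
    call-rate regime of microfluidic SNP genotyping).
    """

    n_populations: int = 3
    n_loci: int = 2000
    fst: float | tuple[float, float] | np.ndarray = (0.2, 0.7)
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    sample_sizes: tuple[int, ...] = (20, 20, 10)
    missing_rate: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ValueError("need at least one population")
        if self.n_loci < 1:
            raise ValueError("need at least one locus")
        lo, hi = self.ancestral_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie in (0, 0.5]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if len(self.sample_sizes) != self.n_populations:
            raise ValueError("sample_sizes length must equal n_populations")
        if any(n < 1 for n in self.sample_sizes):
            raise ValueError("sample sizes must be >= 1")
        f = np.asarray(self.fst, dtype=float)
        if np.any(f < 0) or np.any(f >= 1):
            raise ValueError("divergence F values must be in [0, 1)")


@dataclass
class FrequencyTable:
    """Per-population allele frequencies, one column per locus."""

    ancestral: np.ndarray  # (L,)
    pop: np.ndarray  # (K, L)
    fst: np.ndarray  # (L,) generating divergence parameter per locus
    locus_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ancestral = np.asarray(self.ancestral, dtype=float)
        self.pop = np.asarray(self.pop, dtype=float)
        self.fst = np.asarray(self.fst, dtype=float)
        if self.pop.ndim != 2 or self.pop.shape[1] != self.ancestral.shape[0]:
            raise ValueError("pop must be (K, L) matching ancestral length")
        if np.any(self.pop < 0) or np.any(self.pop > 1):
            raise ValueError("frequencies must lie in [0, 1]")
        if not self.locus_ids:
            self.locus_ids = [f"snp_{i:05d}" for i in range(self.n_loci)]

    @property
    def n_populations(self) -> int:
        return self.pop.shape[0]

    @property
    def n_loci(self) -> int:
        return self.pop.shape[1]


@dataclass
class ReplicateSpec:
    """Repeated-genotyping design: R runs per sample with per-allele error.

    ``allele_error_rate`` is the probability that a single called allele copy
    is flipped to the other allele; modelling the error per allele rather than
    per genotype biases errors toward heterozygote miscalls, like real
    allele-specific PCR.  ``dropout_rate`` is the probability a call is
    missing in a given replicate.
    """

    n_replicates: int = 4
    allele_error_rate: float = 0.05
    dropout_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least two replicates")
        for name in ("allele_error_rate", "dropout_rate"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1)")


def simulate_frequencies(config: SimulationConfig) -> FrequencyTable:
    """Draw ancestral and population allele frequencies (Balding-Nichols).

    Per locus: the ancestral frequency is uniform on ``ancestral_maf_range``;
    each population frequency is an independent Beta draw around it with the
    locus' divergence parameter F.  ``F = 0`` yields the ancestral frequency
    exactly (no divergence); ``F = 1`` is rejected as degenerate.
    """
    rng = _substream(config.seed, "frequencies")
    L, K = config.n_loci, config.n_populations
    p_anc = rng.uniform(*config.ancestral_maf_range, size=L)

    f = np.asarray(config.fst, dtype=float)
    if f.ndim == 0:
        f_loc = np.full(L, float(f))
    elif f.shape == (2,):
        f_loc = rng.uniform(f[0], f[1], size=L)
    elif f.shape == (L,):
        f_loc = f.copy()
    else:
        raise ValueError("fst must be a scalar, a (low, high) pair, or a length-L array")
    if np.any(f_loc >= 1):
        raise ValueError("F = 1 is degenerate under Balding-Nichols")

    pop = np.empty((K, L))
    nonzero = f_loc > 0
    pop[:, ~nonzero] = p_anc[~nonzero]
    if nonzero.any():
        ratio = (1.0 - f_loc[nonzero]) / f_loc[nonzero]
        alpha = p_anc[nonzero] * ratio
        beta = (1.0 - p_anc[nonzero]) * ratio
        pop[:, nonzero] = rng.beta(alpha, beta, size=(K, nonzero.sum()))
    return FrequencyTable(ancestral=p_anc, pop=pop, fst=f_loc)


def _locus_metadata(locus_ids: list[str], rng: np.random.Generator,
                    locus_length: int = 120) -> pd.DataFrame:
    """Assign SNPs to pseudo RAD loci with offsets, emulating short-read loci.

    Consecutive SNPs are grouped into RAD loci carrying 1-3 SNPs each, with
    1-based offsets drawn within a ``locus_length`` bp locus; this gives the
    assay-spacing rule something real to act on.
    """
    contigs, offsets = [], []
    i, contig_no = 0, 0
    L = len(locus_ids)
    while i < L:
        k = min(int(rng.integers(1, 4)), L - i)
        pos = np.sort(rng.choice(np.arange(1, locus_length + 1), size=k, replace=False))
        for p in pos:
            contigs.append(f"RADloc_{contig_no:05d}")
            offsets.append(int(p))
        contig_no += 1
        i += k
    ref = rng.choice(list("ACGT"), size=L)
    alt_shift = rng.integers(1, 4, size=L)
    bases = np.array(list("ACGT"))
    base_idx = {b: i for i, b in enumerate("ACGT")}
    alt = bases[(np.array([base_idx[b] for b in ref]) + alt_shift) % 4]
    return pd.DataFrame(
        {
            "contig": contigs,
            "pos": offsets,
            "ref": ref,
            "alt": alt,
            "position_in_locus": offsets,
        },
        index=pd.Index(locus_ids),
    )


def simulate_genotypes(
    freqs: FrequencyTable,
    sample_sizes: tuple[int, ...] | list[int],
    missing_rate: float = 0.0,
    seed: int | None = None,
    group_names: list[str] | None = None,
    role: str = "control",
) -> tuple[GenotypeMatrix, PopulationMap]:
    """Draw Hardy-Weinberg genotypes from population frequencies.

    The genotype of an individual from population k at locus l is
    Binomial(2, p_kl); calls are then independently masked with
    ``missing_rate``.
    """
    if len(sample_sizes) != freqs.n_populations:
        raise ValueError("sample_sizes length must equal number of populations")
    rng = _substream(seed, "genotypes")
    K, L = freqs.n_populations, freqs.n_loci
    group_names = group_names or [f"pop{k + 1}" for k in range(K)]

    blocks, samples, rows = [], [], []
    for k, n in enumerate(sample_sizes):
        g = rng.binomial(2, freqs.pop[k], size=(n, L)).astype(np.int8)
        blocks.append(g)
        for j in range(n):
            sid = f"{group_names[k]}_{j + 1:03d}"
            samples.append(sid)
            rows.append((sid, group_names[k], role))
    codes = np.vstack(blocks)
    if missing_rate > 0:
        codes[rng.random(codes.shape) < missing_rate] = MISSING

    loci_meta = _locus_metadata(list(freqs.locus_ids), _substream(seed, "locus-meta"))
    m = GenotypeMatrix(sample_ids=samples, locus_ids=list(freqs.locus_ids),
                       codes=codes, loci=loci_meta)
    popmap = PopulationMap(pd.DataFrame(rows, columns=["sample", "group", "role"]))
    return m, popmap


def simulate_admixed(
    q: np.ndarray | list[float],
    freqs: FrequencyTable,
    seed: int | None = None,
    n_samples: int = 1,
) -> np.ndarray:
    """Draw genotype row(s) for admixed individuals with ancestry fractions q.

    Each of the two allele copies at a locus picks its source population with
    probability ``q_k`` and is then Bernoulli(p_kl).  ``q = e_k`` reduces to a
    pure draw from population k.

    Returns an ``(L,)`` code vector for ``n_samples == 1``, else ``(n, L)``.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("ancestry fractions must be non-negative")
    if q.shape != (freqs.n_populations,):
        raise ValueError("q must have one entry per population")
    if not np.isclose(q.sum(), 1.0):
        raise ValueError("ancestry fractions must sum to 1")
    rng = _substream(seed, "admixed")
    L = freqs.n_loci
    out = np.zeros((n_samples, L), dtype=np.int8)
    for copy in range(2):  # two independent allele copies
        src = rng.choice(freqs.n_populations, size=(n_samples, L), p=q)
        p = freqs.pop[src, np.arange(L)[None, :]]
        out += (rng.random((n_samples, L)) < p).astype(np.int8)
    return out[0] if n_samples == 1 else out


def simulate_replicates(
    truth: GenotypeMatrix,
    spec: ReplicateSpec | None = None,
    seed: int | None = None,
) -> ReplicateSet:
    """Replicate each sample's genotypes R times with per-allele error.

    Each allele copy of each called genotype flips independently with
    ``allele_error_rate`` (so a homozygote becomes a het with probability
    ~2e); each replicate call independently drops out with ``dropout_rate``.
    Missing truth stays missing.
    """
    spec = spec or ReplicateSpec()
    rng = _substream(seed, "replicates")
    n, L, R = truth.n_samples, truth.n_loci, spec.n_replicates
    g = truth.codes
    called = g != MISSING
    alt = np.where(called, g, 0)

    reps = np.empty((n, R, L), dtype=np.int8)
    for r in range(R):
        flips_alt = rng.binomial(alt, spec.allele_error_rate)
        flips_ref = rng.binomial(np.where(called, 2 - alt, 0), spec.allele_error_rate)
        noisy = alt - flips_alt + flips_ref
        noisy = np.where(called, noisy, MISSING).astype(np.int8)
        if spec.dropout_rate > 0:
            noisy[rng.random((n, L)) < spec.dropout_rate] = MISSING
        reps[:, r, :] = noisy
    meta = pd.DataFrame(
        [(s, r, "chip1", 1) for s in truth.sample_ids for r in range(R)],
        columns=["sample", "replicate", "chip", "partition"],
    )
    return ReplicateSet(sample_ids=list(truth.sample_ids),
                        locus_ids=list(truth.locus_ids), codes=reps,
                        replicate_meta=meta)


def simulate_study(
    config: SimulationConfig,
    replicate_spec: ReplicateSpec | None = None,
    controls_per_population: int = 3,
) -> dict:
    """Convenience end-to-end draw: frequencies, genotypes, replicates.

    The first ``controls_per_population`` samples of each population are
    flagged as genotype reference controls; the remainder are unknowns.
    """
    freqs = simulate_frequencies(config)
    m, popmap = simulate_genotypes(freqs, config.sample_sizes,
                                   config.missing_rate, seed=config.seed)
    roles = {}
    for g, members in popmap.controls_by_group().items():
        for i, s in enumerate(members):
            roles[s] = "control" if i < controls_per_population else "unknown"
    popmap = popmap.with_roles(roles)
    out = {"freqs": freqs, "genotypes": m, "popmap": popmap}
    if replicate_spec is not None:
        out["replicates"] = simulate_replicates(m, replicate_spec, seed=config.seed)
    return out
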