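# Methods

This note documents the models, estimators and design choices behind
`panelforge`, in the spirit of the methods documentation of simulation and
statistics packages: what is computed, under which assumptions, which knobs
matter, and what the synthetic test bed does and does not show.

## Data model

Genotypes are biallelic dosage codes {0, 1, 2} with a missing sentinel,
stored sample × locus (`GenotypeMatrix`), optionally with per-call read
depth, phred genotype quality and (ref, alt) allele depths, and per-locus
coordinates (contig = RAD locus, 1-based offset within it). The code counts
the alternate allele as written in the source VCF; minor-allele frequency is
derived downstream, so allele orientation never affects any statistic.
Sample metadata is a population map (sample, group, role) with roles
`control` (ascertainment/reference individuals), `unknown`, `outgroup` and
`ntc`. Repeated genotyping runs are a sample × replicate × locus stack
(`ReplicateSet`).

## Synthetic cohort generator

The generator emulates the study design the pipeline targets, not sequence
data: K diverged populations genotyped at L biallelic SNPs, with replicated
panel genotyping.

- **Divergence model.** Balding–Nichols: per locus, an ancestral frequency
  p is drawn uniformly from `ancestral_maf_range` (default [0.05, 0.5]) and
  each population's frequency from Beta(p(1−F)/F, (1−p)(1−F)/F), where F is
  the locus' divergence parameter. F = 0 collapses to no divergence; F = 1
  is rejected. The model was chosen because its parameter directly targets
  per-locus F_ST, which is the axis the panel-selection method works along.
  The multilocus (ratio-of-sums) Weir–Cockerham estimate recovers the
  generating mean F; note that the *mean of per-locus* theta estimates is
  biased slightly low (a Jensen effect of the per-locus ratio), so
  calibration checks use the multilocus estimator.
- **Defaults as study conditions.** K = 3 populations, L = 2000 discovery
  loci, F ~ U(0.2, 0.7), sample sizes 20/20/10 (the real discovery panels in
  this kind of study are far smaller, 3/3/2; the larger default gives the
  statistics room to behave), missing rate 0.02 (the ~98% call-rate regime
  of microfluidic genotyping), 4 replicates per sample, per-allele error
  0.05 (middle of the 2–10% band typical of allele-specific PCR panels),
  dropout 0.02 per call.
- **Replicate error is per allele copy,** not per genotype: each called
  allele flips independently with the error rate, so homozygotes miscall to
  heterozygotes at ~2e and heterozygote miscalls dominate — the error
  profile of allele-specific PCR. The expected allele-mismatch rate against
  truth is e for homozygotes and e(1−e) per copy for heterozygotes, which is
  the closed form the tests check Match Scores against.
- **Admixed individuals** draw each of their two allele copies from
  population k with probability q_k, then Bernoulli(p_kl).
- **RAD geometry.** SNPs are grouped into pseudo RAD loci of 1–3 SNPs with
  offsets within a 120-bp locus, so the assay spacing rule has realistic
  input.
- **Reproducibility.** One integer seed; every stage derives a named
  substream via a CRC-keyed `SeedSequence`, so outputs are bit-reproducible
  and stages are independently stable.

What the generator does **not** emulate: linkage and coalescent history
(loci are independent), locus dropout correlated with divergence (null
alleles), batch effects, and ascertainment bias from tiny discovery panels.
Passing tests therefore show the estimators and decision rules behave
correctly under the assumed statistical structure — not that a real 3RAD
experiment will achieve the same accuracies.

## Filters

Stage order is fixed and documented rather than inferred: per-call quality
mask (depth < 10 or GQ < 30 → missing; boundaries inclusive) → heterozygote
allele-balance mask (ref-read fraction outside [0.25, 0.75] → missing;
homozygotes untouched) → minor-allele-count filter (MAC < 2 on post-masking
calls → locus dropped) → per-locus missingness (> 0.5 missing → dropped).
MAC is counted after masking because masking changes the calls MAC is
defined over. Missingness is per locus; an optional per-sample cutoff exists
but is off by default. The cascade only ever turns calls missing or drops
loci, and is idempotent.

## Diversity and differentiation

- H_O = heterozygotes / N; H_S = (2N/(2N−1))(1 − p² − q²) (Nei's unbiased
  correction — this, not the uncorrected gene diversity, reproduces
  published panel tables); PIC = 1 − p² − q² − 2p²q² (Botstein's biallelic
  form). Monomorphic loci score 0; loci with no calls are flagged missing.
  N varies per locus (pairwise-complete handling of missing calls).
- Weir–Cockerham (1984) variance components a, b, c per locus from
  per-group sample sizes, allele frequencies and observed heterozygote
  frequencies; θ = a/(a+b+c), undefined (missing) when the denominator is
  zero; groups without data at a locus drop out of r. Multilocus and
  pairwise estimates use the ratio of sums Σa/Σ(a+b+c). Pairwise 95% CIs are
  percentile bootstrap over loci (default 1000 resamples, seeded);
  significance = CI excludes zero. θ is invariant to allele relabelling and
  to duplicating loci (ratio property); fixed opposite groups give θ = 1;
  identical groups give θ ≤ 0 (the estimator is allowed to go negative).
- Nei's D_A = 1 − (1/L) Σ_l Σ_alleles √(x y) and Nei's identity
  I = j_xy/√(j_x j_y) are computed from group frequency tables over shared
  loci.

## Panel selection

Per-locus θ windows define candidate subsets (default windows (0.3, 0.5),
(0.5, 0.7), (0.8, 1.0); subset size 200). Inside an over-full window the
default choice is a seeded uniform draw (a "closest to window midpoint" rule
is available); windows are free parameters. Each subset is scored by PCA on
mean-imputed, column-centred codes (no variance scaling, so high-F_ST loci
keep their weight): score 1 = % variance on PC1+PC2, score 2 = silhouette of
the known group labels in the PC1–PC2 plane. "Three distinct clusters" is
operationalised as silhouette ≥ 0.5 (configurable) — a quantitative stand-in
for the visual judgement these panels are usually chosen by.

Diagnostic loci are those where every control of one species is homozygous
for one allele and every other control homozygous for the other, with no
missing control calls — the strict fixation pattern that makes a SNP usable
as a single-locus species test. The spacing rule removes any candidate with
another SNP within 30 bp on the same RAD locus (inclusive boundary; such
neighbours sit in primer binding sites), counting non-candidate SNPs too.

Final assembly ranks subsets by (distinct-cluster flag, PC1+PC2 variance),
preferring subsets that can fill the requested panel size; within the
winning subset, diagnostic loci come first, then descending θ — the printed
procedure this mirrors does not state its within-subset rule, so this
ranking is a documented choice. Extras (e.g. barcode SNPs) are appended and
de-duplicated, and the assembled panel is re-scored so the distinct-cluster
criterion can be verified on the panel itself.

## Replicate consensus

QC order: replicate exclusion (call rate ≤ 85%) → locus success filter
(< 80% of reactions → removed; exactly 80% retained) → consensus. Consensus
per sample × locus: ≥ 2 replicates missing → insufficient/missing; otherwise
majority genotype; genotype-class ties resolve by the most prevalent allele,
which yields the standard patterns (3 hom + 1 het → hom; 2 het + 2 opposite
homs → het) and leaves a 2-vs-2 opposite-homozygote split with no
heterozygotes as missing (logged). With three retained replicates the same
rules apply (majority of 3; ≥ 2 missing → missing). Match Score is allele-
level — a het/hom mismatch costs half a genotype — so it coincides exactly
with 1 − allele-sharing distance on the same pair, an identity the tests
assert; error rate = 100 − Match Score by construction. NTC handling is a
data-level role flag; fluorescence is not modelled.

## Assignment and clustering

- **Allele sharing.** Pairwise similarity per locus = shared allele
  copies / 2 ∈ {0, ½, 1}; distance = 1 − mean over loci typed in both.
  "Shared genotypic information" with a species = mean similarity with that
  species' controls, in percent (a max-over-controls variant is available);
  assignment requires the top fraction ≥ 80%, otherwise the sample is
  reported unassigned with its two top fractions — how admixed or
  intermediate individuals present. The per-group fractions are *not*
  normalised to sum to 100.
- **UPGMA** is implemented directly (size-weighted average linkage,
  ultrametric heights = half the joining distance) with a lexicographic
  smallest-pair tie-break so trees are deterministic; scipy's average
  linkage is the independent cross-check in the tests. Bootstrap supports
  resample loci (not samples), recompute the distance and tree, and count
  bipartition recovery.
- **Ordination.** PCoA is classical metric MDS on the distance matrix
  (negative-eigenvalue axes dropped with a note); PCA as in panel scoring.
- **Admixture EM.** Binomial mixture: dosage g_il ~ Binomial(2, Σ_k q_ik
  f_kl). Block EM updates of Q (rows on the simplex) and F with
  responsibilities split by allele type; missing genotypes drop out of the
  likelihood; the log-likelihood is non-decreasing every iteration and K = 1
  reduces to observed frequencies in closed form. Convergence = loglik gain
  < tol (default 1e-4, max 500 iterations); non-convergence returns the
  current state with a warning. Samples with max_k q < 0.8 are flagged
  admixed.
- **K selection** masks 20% of non-missing genotype entries, fits the model,
  predicts masked dosages by 2·Σ_k q_ik f_kl, and scores the mean squared
  prediction error; best K minimises the mean CV error over replicates
  (default 5). CV fits use a looser tolerance (1e-2, 200 iterations) —
  the error curve needs a stable plateau, not a fully converged optimum.
- **MLG matching** groups identical genotype vectors (exact mode by
  default; a wildcard mode lets missing match anything). **Frequency
  assignment** scores each sample's HWE log-likelihood under each control
  group's frequencies, leave-one-out for controls, with zero/one
  frequencies floored at 1/(2N+1).

## Pipeline and problem sizes

`run_discovery` (simulate-or-load → filter → stats → panel) and
`run_identification` (consensus → QC → assignment → tree/PCoA/admixture) are
driven by one config and one seed; every artifact carries the seed and a
config hash (output paths excluded from the hash). Samples with a
genotyping rate below 0.4 after consensus — the signature of non-target
(outgroup) material in a genus-specific panel — are excluded and reported.

Default desk-scale problem sizes (2000 discovery loci, 50 samples, panels
of ~19–24 SNPs, 100–200 bootstrap/CV replicates) complete in seconds on one
CPU; the full simulated pipeline stays well under five minutes. The
acceptance study for assignment accuracy uses 400-locus cohorts over 20
seeds with a single inclusive θ window (0.2, 1.0): under Balding–Nichols,
strongly diagnostic loci are abundant and the windowing is a free parameter,
so the study exercises the ranking (diagnostic first, then θ) rather than a
particular window choice.

## Known limitations

Biallelic SNPs only (multi-allelic records are skipped on read); no
phasing, imputation or LD handling; UPGMA bootstrap is O(boot × n² × L);
the EM is a local optimiser (seeded restarts are the caller's
responsibility); the allele-sharing threshold (80%) and admixture cutoff
(q < 0.8) are conventions of the target workflow, not estimated quantities;
and conclusions about real 3RAD data are limited by what the generator does
not model (see above).
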