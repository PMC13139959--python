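"""Read and write the formats the pipeline touches.

Supported: VCF 4.x (read via cyvcf2, only biallelic SNP records kept), the
long-format genotype-table CSV dialect of microfluidic SNP-type exports
(columns sample, assay, call with allele-pair calls like ``A:G`` and
``No Call``; repeated (sample, assay) rows stack into replicates), the
population-map TSV (sample, group, role) and Newick trees.  Coordinates are
1-based inclusive (the VCF convention) everywhere, and round-trips preserve
codes, ids, ordering and missingness exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import MISSING, GenotypeMatrix, PopulationMap, ReplicateSet

logger = logging.getLogger(__name__)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_genotype_table",
    "write_genotype_table",
    "read_population_map",
    "write_population_map",
    "write_newick",
]


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load biallelic SNP records from a VCF into a genotype matrix.

    Multi-allelic or non-SNP records are skipped with a logged count; missing
    GT becomes the missing code; GT/DP/GQ/AD are parsed when present and
    sample order is preserved.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    locus_ids, codes, depth, quality, ad = [], [], [], [], []
    meta = []
    skipped = 0
    has_dp = has_gq = has_ad = False
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            skipped += 1
            continue
        lid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        locus_ids.append(lid)
        g = var.gt_types.astype(np.int8)  # gts012: 0,1,2, 3=missing
        g[g == 3] = MISSING
        codes.append(g)
        meta.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        def fmt(tag):
            try:
                return var.format(tag)
            except KeyError:
                return None

        dp = fmt("DP")
        gq = fmt("GQ")
        adv = fmt("AD")
        depth.append(dp[:, 0].astype(float) if dp is not None else np.full(len(samples), np.nan))
        quality.append(gq[:, 0].astype(float) if gq is not None else np.full(len(samples), np.nan))
        if adv is not None and adv.shape[1] >= 2:
            has_ad = True
            ad.append(adv[:, :2].astype(float))
        else:
            ad.append(np.full((len(samples), 2), np.nan))
        has_dp |= dp is not None
        has_gq |= gq is not None
    if skipped:
        logger.info("skipped %d non-biallelic/non-SNP records", skipped)
    if not locus_ids:
        raise ValueError(f"no biallelic SNP records in {path}")
    loci = pd.DataFrame(meta, columns=["contig", "pos", "ref", "alt"])
    loci["position_in_locus"] = loci["pos"]
    arr = np.array(codes).T
    ad_arr = np.swapaxes(np.array(ad), 0, 1)
    dep = np.array(depth).T
    qua = np.array(quality).T
    return GenotypeMatrix(
        sample_ids=samples,
        locus_ids=locus_ids,
        codes=arr,
        depth=dep if has_dp else None,
        quality=qua if has_gq else None,
        allele_depths=ad_arr if has_ad else None,
        loci=loci,
    )


def write_vcf(m: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as a minimal VCF 4.2 file (one record per locus)."""
    path = Path(path)
    loci = m.loci if m.loci is not None else pd.DataFrame(
        {"contig": m.locus_ids, "pos": 1, "ref": "A", "alt": "G"},
        index=pd.Index(m.locus_ids),
    )
    contigs = list(dict.fromkeys(loci["contig"]))
    fmt_fields = ["GT"]
    if m.depth is not None:
        fmt_fields.append("DP")
    if m.quality is not None:
        fmt_fields.append("GQ")
    if m.allele_depths is not None:
        fmt_fields.append("AD")
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=panelforge\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if "DP" in fmt_fields:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if "GQ" in fmt_fields:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        if "AD" in fmt_fields:
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(m.sample_ids) + "\n")
        for j, lid in enumerate(m.locus_ids):
            row = loci.iloc[j]
            fields = [str(row["contig"]), str(int(row["pos"])), lid,
                      str(row.get("ref", "A")), str(row.get("alt", "G")),
                      ".", "PASS", ".", ":".join(fmt_fields)]
            for i in range(m.n_samples):
                parts = [gt_str[int(m.codes[i, j])]]
                if "DP" in fmt_fields:
                    d = m.depth[i, j]
                    parts.append("." if np.isnan(d) else str(int(d)))
                if "GQ" in fmt_fields:
                    q = m.quality[i, j]
                    parts.append("." if np.isnan(q) else str(int(q)))
                if "AD" in fmt_fields:
                    a = m.allele_depths[i, j]
                    parts.append("." if np.isnan(a).any()
                                 else f"{int(a[0])},{int(a[1])}")
                fields.append(":".join(parts))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Long-format genotype tables (microfluidic export dialect)
# ---------------------------------------------------------------------------

_NO_CALL = {"no call", "nocall", "ntc", "invalid", ""}


def _call_to_code(call: str, ref: str, alt: str, assay: str) -> int:
    call = str(call).strip()
    if call.lower() in _NO_CALL or call.lower() == "nan":
        return MISSING
    alleles = call.replace("|", ":").split(":")
    if len(alleles) != 2:
        raise ValueError(f"{assay}: malformed call {call!r}")
    code = 0
    for a in alleles:
        a = a.strip()
        if a == alt:
            code += 1
        elif a != ref:
            raise ValueError(f"{assay}: allele {a!r} not in dictionary ({ref}/{alt})")
    return code


def read_genotype_table(path: str | Path,
                        allele_map: dict[str, tuple[str, str]] | None = None
                        ) -> GenotypeMatrix | ReplicateSet:
    """Read a long-format genotype table (sample, assay, call).

    ``allele_map`` maps each assay to its (ref, alt) allele letters; when
    omitted, a ``ref``/``alt`` column pair in the file is used.  Allele-pair
    strings become dosage codes, ``No Call``/blank become missing, and
    repeated (sample, assay) rows stack into a ReplicateSet (otherwise a
    plain GenotypeMatrix is returned).
    """
    t = pd.read_csv(path, dtype=str)
    t.columns = [c.strip().lower() for c in t.columns]
    required = {"sample", "assay", "call"}
    if not required.issubset(t.columns):
        raise ValueError(f"genotype table needs columns {sorted(required)}")
    if allele_map is None:
        if {"ref", "alt"}.issubset(t.columns):
            allele_map = {
                a: (grp["ref"].iloc[0], grp["alt"].iloc[0])
                for a, grp in t.groupby("assay", sort=False)
            }
        else:
            raise ValueError("allele_map required when the table has no ref/alt columns")

    samples = list(dict.fromkeys(t["sample"]))
    assays = list(dict.fromkeys(t["assay"]))
    max_rep = int(t.groupby(["sample", "assay"]).size().max())
    codes = np.full((len(samples), max_rep, len(assays)), MISSING, dtype=np.int8)
    s_idx = {s: i for i, s in enumerate(samples)}
    a_idx = {a: j for j, a in enumerate(assays)}
    counter: dict[tuple[str, str], int] = {}
    meta_rows = []
    for row in t.itertuples(index=False):
        s, a, call = row.sample, row.assay, row.call
        if a not in allele_map:
            raise ValueError(f"assay {a!r} has no allele dictionary entry")
        r = counter.get((s, a), 0)
        counter[(s, a)] = r + 1
        codes[s_idx[s], r, a_idx[a]] = _call_to_code(call, *allele_map[a], a)
        meta_rows.append((s, r,
                          getattr(row, "chip", None), getattr(row, "partition", None)))
    if max_rep == 1:
        return GenotypeMatrix(sample_ids=samples, locus_ids=assays,
                              codes=codes[:, 0, :])
    meta = pd.DataFrame(meta_rows, columns=["sample", "replicate", "chip", "partition"])
    return ReplicateSet(sample_ids=samples, locus_ids=assays, codes=codes,
                        replicate_meta=meta.drop_duplicates(["sample", "replicate"]))


def write_genotype_table(obj: GenotypeMatrix | ReplicateSet, path: str | Path,
                         allele_map: dict[str, tuple[str, str]] | None = None) -> None:
    """Write a matrix or replicate set as the long (sample, assay, call) CSV."""
    if isinstance(obj, GenotypeMatrix):
        locus_ids = obj.locus_ids
        stacks = obj.codes[:, None, :]
        samples = obj.sample_ids
    else:
        locus_ids = obj.locus_ids
        stacks = obj.codes
        samples = obj.sample_ids
    if allele_map is None:
        if isinstance(obj, GenotypeMatrix) and obj.loci is not None \
                and {"ref", "alt"}.issubset(obj.loci.columns):
            allele_map = {l: (obj.loci.loc[l, "ref"], obj.loci.loc[l, "alt"])
                          for l in locus_ids}
        else:
            allele_map = {l: ("A", "G") for l in locus_ids}
    rows = []
    for i, s in enumerate(samples):
        for r in range(stacks.shape[1]):
            for j, a in enumerate(locus_ids):
                ref, alt = allele_map[a]
                code = int(stacks[i, r, j])
                call = {0: f"{ref}:{ref}", 1: f"{ref}:{alt}", 2: f"{alt}:{alt}",
                        MISSING: "No Call"}[code]
                rows.append((s, a, call, ref, alt))
    pd.DataFrame(rows, columns=["sample", "assay", "call", "ref", "alt"]
                 ).to_csv(path, index=False)


def read_population_map(path: str | Path) -> PopulationMap:
    t = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    t.columns = [c.strip().lower() for c in t.columns]
    return PopulationMap(t)


def write_population_map(popmap: PopulationMap, path: str | Path) -> None:
    popmap.table.to_csv(path, sep="\t", index=False)


def write_newick(tree, path: str | Path, with_support: bool = False) -> None:
    """Write an UPGMA tree (or anything with ``to_newick``) to a file."""
    text = tree.to_newick(with_support=with_support) if hasattr(tree, "to_newick") else str(tree)
    Path(path).write_text(text + ("\n" if not text.endswith("\n") else ""))
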