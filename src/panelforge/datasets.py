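"""Published summary data for the 23-assay Greyia species-identification panel.

The panel of 23 SNP Type assays (18 SNPs from 3RAD discovery plus five from
the ITS/trnL-F/matK plant barcodes) was characterised on 73 wild-growing
Greyia trees.  ``greyia_panel_summary`` returns the per-assay summary as
printed for that cohort: sample size N, minor allele frequency, observed
heterozygosity H_O, unbiased gene diversity H_S and PIC, plus the species
each assay diagnoses (GRA = G. radlkoferi, GSU = G. sutherlandii,
GFL = G. flanaganii).

``reconstruct_panel_genotypes`` rebuilds a genotype matrix whose per-locus
composition is implied by the printed N, MAF and H_O columns (minor-allele
count = round(MAF * 2N), heterozygote count = round(H_O * N)); running
``locus_summary`` on it reproduces the printed H_S and PIC columns, which is
the standard self-consistency check for this kind of panel table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

__all__ = ["greyia_panel_summary", "reconstruct_panel_genotypes"]

# assay, diagnostic species, N, MAF, H_O, H_S, PIC over all 73 wild trees
_PANEL_ROWS = [
    ("Greyia_3RAD_D1_16417.28", "GFL", 73, 0.445, 0.836, 0.497, 0.372),
    ("Greyia_3RAD_D1_17901.48", "GSU", 72, 0.194, 0.306, 0.315, 0.264),
    ("Greyia_3RAD_D1_20015.167", "GRA", 73, 0.486, 0.151, 0.503, 0.375),
    ("Greyia_3RAD_D1_16438.7", "GFL", 73, 0.144, 0.014, 0.248, 0.216),
    ("Greyia_3RAD_D1_18402.102", "GSU", 73, 0.233, 0.055, 0.360, 0.293),
    ("Greyia_3RAD_D1_20179.46", "GRA", 73, 0.473, 0.616, 0.502, 0.374),
    ("Greyia_3RAD_D1_16444.229", "GRA", 73, 0.103, 0.151, 0.186, 0.167),
    ("Greyia_3RAD_D1_19009.73", "GFL", 73, 0.226, 0.178, 0.352, 0.289),
    ("Greyia_BarSNP_its2_01", "GFL", 73, 0.240, 0.342, 0.367, 0.298),
    ("Greyia_3RAD_D1_16938.173", "GRA", 73, 0.425, 0.822, 0.492, 0.369),
    ("Greyia_3RAD_D1_19082.71", "GFL", 73, 0.493, 0.521, 0.503, 0.375),
    ("Greyia_BarSNP_its2_02", "GSU", 73, 0.308, 0.507, 0.429, 0.336),
    ("Greyia_3RAD_D1_16946.51", "GSU", 72, 0.493, 0.097, 0.503, 0.375),
    ("Greyia_3RAD_D1_19227.91", "GFL", 73, 0.144, 0.014, 0.248, 0.216),
    ("Greyia_BarSNP_its2_03", "GFL", 73, 0.432, 0.863, 0.494, 0.370),
    ("Greyia_3RAD_D1_17188.43", "GSU", 72, 0.243, 0.042, 0.371, 0.300),
    ("Greyia_3RAD_D1_19287.52", "GSU", 68, 0.404, 0.426, 0.485, 0.366),
    ("Greyia_BarSNP_matK_01", "GFL", 73, 0.144, 0.123, 0.248, 0.216),
    ("Greyia_3RAD_D1_17357.154", "GRA", 70, 0.407, 0.414, 0.486, 0.366),
    ("Greyia_3RAD_D1_19922.176", "GRA", 72, 0.292, 0.111, 0.416, 0.328),
    ("Greyia_BarSNP_trnLH_01", "GSU", 72, 0.236, 0.028, 0.363, 0.296),
    ("Greyia_3RAD_D1_17371.56", "GSU", 73, 0.199, 0.397, 0.321, 0.268),
    ("Greyia_3RAD_D1_19983.195", "GFL", 67, 0.224, 0.239, 0.350, 0.287),
]


def greyia_panel_summary() -> pd.DataFrame:
    """Published per-assay summary statistics over the 73-tree wild cohort."""
    return pd.DataFrame(
        _PANEL_ROWS,
        columns=["assay", "species", "N", "MAF", "H_O", "H_S", "PIC"],
    )


def reconstruct_panel_genotypes(summary: pd.DataFrame | None = None,
                                n_samples: int | None = None) -> GenotypeMatrix:
    """Rebuild a genotype matrix implied by printed (N, MAF, H_O) columns.

    For each assay, minor-allele count m = round(MAF * 2N) and heterozygote
    count h = round(H_O * N) yield (m - h)/2 minor homozygotes (an integer
    for every published row), h heterozygotes and N - h - (m - h)/2 major
    homozygotes; samples beyond N are missing.  Sample identity is not
    recoverable from marginals, so genotypes are laid out locus-wise.
    """
    summary = greyia_panel_summary() if summary is None else summary
    n_samples = int(summary["N"].max()) if n_samples is None else n_samples
    codes = np.full((n_samples, len(summary)), MISSING, dtype=np.int8)
    for j, row in enumerate(summary.itertuples(index=False)):
        n = int(row.N)
        if n > n_samples:
            raise ValueError(f"N={n} exceeds matrix height {n_samples}")
        m = round(row.MAF * 2 * n)
        h = round(row.H_O * n)
        if (m - h) % 2:
            raise ValueError(
                f"{row.assay}: printed MAF/H_O imply a non-integer homozygote count"
            )
        hom_minor = (m - h) // 2
        vec = [2] * hom_minor + [1] * h + [0] * (n - h - hom_minor)
        codes[: n, j] = vec
    return GenotypeMatrix(
        sample_ids=[f"tree_{i + 1:03d}" for i in range(n_samples)],
        locus_ids=summary["assay"].tolist(),
        codes=codes,
    )
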