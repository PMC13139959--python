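"""End-to-end orchestration: simulate -> filter -> stats -> panel (discovery)
and consensus -> assign -> tree/ordination/admixture (identification).

Every run is driven by one ``RunConfig`` and a single global seed; artifacts
are written with a header stamp carrying the seed and a config hash so reruns
are verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assignment as asg
from . import consensus as cns
from . import io as pio
from . import panel as pnl
from . import stats as pst
from .core import GenotypeMatrix, PopulationMap, ReplicateSet
from .filters import FilterConfig, filter_loci
from .simulate import ReplicateSpec, SimulationConfig, simulate_study

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_discovery", "run_identification"]


@dataclass
class RunConfig:
    out_dir: str = "panelforge_out"
    seed: int = 0
    vcf: str | None = None  # discovery input; None -> simulate
    popmap: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    replicates: ReplicateSpec = field(default_factory=ReplicateSpec)
    filters: FilterConfig = field(default_factory=FilterConfig)
    windows: tuple[tuple[float, float], ...] = ((0.3, 0.5), (0.5, 0.7), (0.8, 1.0))
    subset_size: int = 200
    target_size: int = 19
    extra_loci: tuple[str, ...] = ()
    min_gap: int = 30
    assign_threshold: float = 0.80
    outgroup_call_rate: float = 0.4  # samples below this genotyping rate are excluded
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    cv_replicates: int = 5

    def config_hash(self) -> str:
        def default(o):
            return asdict(o) if hasattr(o, "__dataclass_fields__") else str(o)
        d = asdict(self)
        d.pop("out_dir", None)  # where results land does not change them
        blob = json.dumps(d, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stamp(cfg: RunConfig) -> str:
    return f"# panelforge seed={cfg.seed} config={cfg.config_hash()}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(cfg))
        df.to_csv(fh, sep="\t", index=False)


def run_discovery(cfg: RunConfig) -> dict:
    """Discovery phase: genotype source -> filters -> stats -> panel.

    Returns the artifact dict and writes filtered VCF, the per-locus stats
    table, the pairwise F_ST table, and the panel locus list with scores.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.vcf is not None:
        m = pio.read_vcf(cfg.vcf)
        if cfg.popmap is None:
            raise ValueError("popmap path required with a VCF input")
        popmap = pio.read_population_map(cfg.popmap)
    else:
        study = simulate_study(cfg.simulation)
        m, popmap = study["genotypes"], study["popmap"]
        pio.write_vcf(m, out / "discovery.vcf")
        pio.write_population_map(popmap, out / "popmap.tsv")

    filtered, report = filter_loci(m, cfg.filters)
    _write_tsv(report.to_frame(), out / "filter_report.tsv", cfg)
    if filtered.n_loci == 0:
        raise RuntimeError("stage 'filter' failed: no loci survived")

    stats = pst.locus_summary(filtered, popmap)
    _write_tsv(stats, out / "locus_stats.tsv", cfg)
    pw = pst.pairwise_wc_fst(filtered, popmap, n_boot=200, seed=cfg.seed)
    _write_tsv(pd.DataFrame([vars(p) for p in pw]), out / "pairwise_fst.tsv", cfg)

    subsets = []
    for w in cfg.windows:
        spec = pnl.FstWindowSpec(window=w, subset_size=cfg.subset_size)
        sub = pnl.subset_by_fst_window(stats, spec, seed=cfg.seed)
        if sub.locus_ids:
            subsets.append(pnl.score_subset(filtered, sub, popmap))
    if not subsets:
        raise RuntimeError("stage 'panel' failed: no loci in any F_ST window")

    diagnostic = pnl.find_diagnostic_snps(filtered, popmap)
    loci_meta = filtered.loci if filtered.loci is not None else pd.DataFrame()
    spaced_subsets = []
    for s in subsets:
        kept = pnl.apply_spacing_constraint(s.locus_ids, loci_meta, cfg.min_gap)
        spaced_subsets.append(pnl.PanelSubset(kept, s.window, s.pc12_variance,
                                              s.silhouette, s.distinct_clusters))
    panel = pnl.assemble_panel(
        spaced_subsets, filtered, popmap, target_size=cfg.target_size,
        diagnostic=diagnostic, extra_loci=list(cfg.extra_loci), stats=stats,
    )
    panel_df = pd.DataFrame({"locus_id": panel.locus_ids})
    panel_df["diagnostic_for"] = panel_df["locus_id"].map(
        diagnostic.set_index("locus_id")["species"]
        if not diagnostic.empty else {})
    _write_tsv(panel_df, out / "panel_loci.tsv", cfg)
    score_df = pd.DataFrame(
        [{"window": str(s.window), "n_loci": len(s.locus_ids),
          "pc12_variance": s.pc12_variance, "silhouette": s.silhouette,
          "distinct_clusters": s.distinct_clusters} for s in subsets]
        + [{"window": "final_panel", "n_loci": len(panel.locus_ids),
            "pc12_variance": panel.pc12_variance, "silhouette": panel.silhouette,
            "distinct_clusters": panel.distinct_clusters}]
    )
    _write_tsv(score_df, out / "panel_scores.tsv", cfg)
    return {"matrix": filtered, "popmap": popmap, "stats": stats,
            "pairwise_fst": pw, "subsets": subsets, "panel": panel,
            "diagnostic": diagnostic}


def run_identification(cfg: RunConfig, replicates: ReplicateSet,
                       popmap: PopulationMap) -> dict:
    """Identification phase on a panel replicate set with labelled controls.

    Consensus genotypes are built with the replicate/locus QC rules; samples
    with a genotyping rate below ``outgroup_call_rate`` (outgroup-like
    failures) are excluded and reported; the rest are assigned by allele
    sharing and corroborated with UPGMA, PCoA and the admixture EM.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = cns.build_consensus(replicates)
    m = result.consensus

    qc = pd.DataFrame({
        "sample": m.sample_ids,
        "mean_call_rate": result.mean_call_rate.to_numpy(),
        "match_score": result.match_score.to_numpy(),
        "error_rate": result.error_rate.to_numpy(),
        "genotyping_rate": m.call_rate_per_sample(),
    })
    qc["excluded"] = (qc["genotyping_rate"] < cfg.outgroup_call_rate) \
        | qc["sample"].isin(result.failed_samples)
    _write_tsv(qc, out / "qc_report.tsv", cfg)

    keep = qc.loc[~qc["excluded"], "sample"].tolist()
    excluded = qc.loc[qc["excluded"], "sample"].tolist()
    if excluded:
        logger.info("excluded %d low-genotyping-rate samples: %s",
                    len(excluded), excluded)
    m = m.subset(samples=keep)
    pio.write_genotype_table(m, out / "consensus_genotypes.csv")

    if not popmap.controls_by_group():
        raise ValueError("identification requires control samples")
    assignments = asg.assign_by_sharing(m, popmap, threshold=cfg.assign_threshold)
    assign_df = pd.DataFrame(
        [{"sample": a.sample_id,
          **{f"shared_{g}": v for g, v in sorted(a.shared.items())},
          "assigned": a.assigned or "unassigned"} for a in assignments]
    )
    _write_tsv(assign_df, out / "assignments.tsv", cfg)

    tree = asg.upgma_with_support(m, n_boot=100, seed=cfg.seed)
    pio.write_newick(tree, out / "upgma.nwk", with_support=True)

    d = asg.allele_sharing_distance(m)
    coords, var = asg.pcoa(d)
    with open(out / "pcoa.csv", "w") as fh:
        fh.write(_stamp(cfg))
        fh.write("# axis percent variance: "
                 + ", ".join(f"{v:.2f}" for v in var[:4]) + "\n")
        coords.to_csv(fh)

    best_k, curve = asg.select_k(m, k_range=list(cfg.k_range),
                                 replicates=cfg.cv_replicates, seed=cfg.seed)
    _write_tsv(curve, out / "cv_curve.tsv", cfg)
    est = asg.admixture_em(m, best_k, seed=cfg.seed)
    with open(out / "q_matrix.csv", "w") as fh:
        fh.write(_stamp(cfg))
        est.Q.to_csv(fh)

    return {"consensus": result, "matrix": m, "assignments": assignments,
            "tree": tree, "pcoa": (coords, var), "best_k": best_k,
            "cv_curve": curve, "ancestry": est, "excluded": excluded}
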