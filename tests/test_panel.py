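"""F_ST-window subsetting, PCA scoring, diagnostic SNPs, spacing, assembly."""

import numpy as np
import pandas as pd
import pytest

import panelforge as pf
from panelforge.core import GenotypeMatrix, PopulationMap
from panelforge.panel import (FstWindowSpec, PanelSubset, apply_spacing_constraint,
                              assemble_panel, find_diagnostic_snps, score_subset,
                              subset_by_fst_window)

from conftest import make_matrix


@pytest.fixture(scope="module")
def scored_study():
    cfg = pf.SimulationConfig(n_loci=400, sample_sizes=(20, 20, 10),
                              missing_rate=0.02, seed=101)
    study = pf.simulate_study(cfg)
    stats = pf.locus_summary(study["genotypes"], study["popmap"])
    return study, stats


class TestWindowSubsets:
    def test_undersized_window_returns_all_with_warning(self):
        stats = pd.DataFrame({"locus_id": [f"l{i}" for i in range(150)],
                              "theta": 0.4})
        with pytest.warns(UserWarning):
            sub = subset_by_fst_window(stats, FstWindowSpec((0.3, 0.5), 200), seed=0)
        assert len(sub.locus_ids) == 150

    def test_empty_window_warns(self):
        stats = pd.DataFrame({"locus_id": ["a", "b"], "theta": [0.1, 0.2]})
        with pytest.warns(UserWarning):
            sub = subset_by_fst_window(stats, FstWindowSpec((0.8, 1.0)), seed=0)
        assert sub.locus_ids == []

    def test_subset_within_brute_force_eligible_set(self, scored_study):
        _, stats = scored_study
        spec = FstWindowSpec((0.5, 0.7), subset_size=50)
        sub = subset_by_fst_window(stats, spec, seed=1)
        eligible = set(stats.loc[stats["theta"].between(0.5, 0.7), "locus_id"])
        assert set(sub.locus_ids) <= eligible
        assert len(sub.locus_ids) == min(50, len(eligible))

    def test_seeded_draw_deterministic(self, scored_study):
        _, stats = scored_study
        spec = FstWindowSpec((0.2, 0.9), subset_size=30)
        a = subset_by_fst_window(stats, spec, seed=7)
        b = subset_by_fst_window(stats, spec, seed=7)
        assert a.locus_ids == b.locus_ids

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            FstWindowSpec((0.5, 0.5))


class TestScoring:
    def test_fixed_diverged_groups_near_perfect_silhouette(self):
        codes = np.vstack([np.zeros((5, 20)), np.ones((5, 20)) * 2,
                           np.tile([0, 2], (5, 10))])
        m = make_matrix(codes.astype(int))
        popmap = PopulationMap.from_items(
            {f"s{i}": f"g{i // 5}" for i in range(15)})
        scored = score_subset(m, PanelSubset(m.locus_ids), popmap)
        assert scored.silhouette > 0.9
        assert scored.distinct_clusters

    def test_panmictic_silhouette_near_zero(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.integers(0, 3, size=(30, 40)))
        popmap = PopulationMap.from_items(
            {f"s{i}": f"g{i % 3}" for i in range(30)})
        scored = score_subset(m, PanelSubset(m.locus_ids), popmap)
        assert abs(scored.silhouette) < 0.2
        assert not scored.distinct_clusters

    def test_intermediate_window_beats_sparse_noisy_high_window(self):
        """When truly high-F loci are rare and noisy, the panel is assembled
        from the intermediate-F subset — the motivating selection pattern."""
        rng = np.random.default_rng(5)
        L_mid, L_high = 200, 6
        fst = np.concatenate([np.full(L_mid, 0.35), np.full(L_high, 0.9)])
        cfg = pf.SimulationConfig(n_loci=L_mid + L_high, fst=fst,
                                  sample_sizes=(10, 10, 10),
                                  missing_rate=0.0, seed=5)
        fr = pf.simulate_frequencies(cfg)
        m, popmap = pf.simulate_genotypes(fr, cfg.sample_sizes, 0.0, seed=5)
        # the few high-F loci are unreliable: most calls drop out
        hi = m.locus_index(m.locus_ids[L_mid:])
        drop = rng.random((m.n_samples, L_high)) < 0.85
        m.codes[:, hi] = np.where(drop, -1, m.codes[:, hi])
        stats = pf.locus_summary(m, popmap)
        mid = score_subset(m, subset_by_fst_window(
            stats, FstWindowSpec((0.3, 0.5), 200), seed=1), popmap)
        with pytest.warns(UserWarning):
            high = score_subset(m, subset_by_fst_window(
                stats, FstWindowSpec((0.8, 1.0), 200), seed=1), popmap)
        assert len(high.locus_ids) < 19  # cannot fill a panel
        panel = assemble_panel([mid, high], m, popmap, target_size=19,
                               stats=stats)
        assert set(panel.locus_ids) <= set(mid.locus_ids)
        assert panel.distinct_clusters


class TestDiagnosticSnps:
    def test_planted_diagnostic_loci_recovered_exactly(self):
        rng = np.random.default_rng(3)
        n_per, L = 3, 40
        codes = rng.integers(0, 3, size=(3 * n_per, L))
        planted = [2, 11, 17, 25, 33]
        for j in planted:
            codes[:, j] = 0
            codes[3:6, j] = 2  # group g1 fixed alternate, others fixed ref
        m = make_matrix(codes)
        popmap = PopulationMap.from_items(
            {f"s{i}": f"g{i // n_per}" for i in range(9)})
        diag = find_diagnostic_snps(m, popmap)
        recovered = {r.locus_id for r in diag.itertuples()}
        # brute force: enumerate every locus with the fixed-opposite pattern
        expected = set()
        for j in range(L):
            col = codes[:, j]
            groups = [col[:3], col[3:6], col[6:]]
            for g_idx in range(3):
                own = groups[g_idx]
                others = np.concatenate([groups[k] for k in range(3) if k != g_idx])
                for allele in (0, 2):
                    if np.all(own == allele) and np.all(others == 2 - allele):
                        expected.add(f"loc{j}")
        assert recovered == expected
        assert {f"loc{j}" for j in planted} <= recovered
        assert set(diag.loc[diag["locus_id"].isin(
            [f"loc{j}" for j in planted]), "species"]) == {"g1"}

    def test_one_heterozygous_control_spoils_diagnosis(self):
        codes = np.array([[0], [0], [0], [2], [2], [1]])
        m = make_matrix(codes)
        popmap = PopulationMap.from_items(
            {f"s{i}": ("A" if i < 3 else "B") for i in range(6)})
        assert find_diagnostic_snps(m, popmap).empty


class TestSpacing:
    def _meta(self, positions, contig="RAD1"):
        return pd.DataFrame(
            {"contig": contig, "position_in_locus": positions},
            index=pd.Index([f"snp{i}" for i in range(len(positions))]),
        )

    def test_close_pair_both_removed(self):
        meta = self._meta([10, 25])
        assert apply_spacing_constraint(["snp0", "snp1"], meta) == []

    def test_distant_pair_kept(self):
        meta = self._meta([10, 50])
        assert apply_spacing_constraint(["snp0", "snp1"], meta) == ["snp0", "snp1"]

    def test_non_candidate_neighbour_also_spoils(self):
        meta = self._meta([10, 25])
        assert apply_spacing_constraint(["snp0"], meta) == []

    def test_matches_brute_force_pairwise_check(self):
        rng = np.random.default_rng(8)
        contigs = [f"RAD{i // 4}" for i in range(40)]
        pos = rng.integers(1, 120, size=40)
        meta = pd.DataFrame({"contig": contigs, "position_in_locus": pos},
                            index=pd.Index([f"snp{i}" for i in range(40)]))
        cands = [f"snp{i}" for i in range(0, 40, 2)]
        got = apply_spacing_constraint(cands, meta, min_gap=30)
        expected = []
        for c in cands:
            ci, cp = meta.loc[c, "contig"], meta.loc[c, "position_in_locus"]
            ok = True
            for other in meta.index:
                if other == c or meta.loc[other, "contig"] != ci:
                    continue
                if abs(meta.loc[other, "position_in_locus"] - cp) <= 30:
                    ok = False
            if ok:
                expected.append(c)
        assert got == expected


class TestAssembly:
    def test_target_plus_extras_deduplicated(self, scored_study):
        study, stats = scored_study
        m, popmap = study["genotypes"], study["popmap"]
        sub = subset_by_fst_window(stats, FstWindowSpec((0.2, 1.0), 200), seed=0)
        scored = score_subset(m, sub, popmap)
        extras = [m.locus_ids[0], scored.locus_ids[0]]  # second overlaps
        panel = assemble_panel([scored], m, popmap, target_size=19,
                               extra_loci=extras, stats=stats)
        assert len(panel.locus_ids) == len(set(panel.locus_ids))
        assert 19 <= len(panel.locus_ids) <= 21
        assert m.locus_ids[0] in panel.locus_ids

    def test_oversized_target_fatal(self, scored_study):
        study, stats = scored_study
        m, popmap = study["genotypes"], study["popmap"]
        sub = PanelSubset(m.locus_ids[:5])
        scored = score_subset(m, sub, popmap)
        with pytest.raises(ValueError):
            assemble_panel([scored], m, popmap, target_size=10)

    def test_small_panel_silhouette_close_to_subset(self, scored_study):
        study, stats = scored_study
        m, popmap = study["genotypes"], study["popmap"]
        sub = subset_by_fst_window(stats, FstWindowSpec((0.2, 1.0), 200), seed=0)
        scored = score_subset(m, sub, popmap)
        panel = assemble_panel([scored], m, popmap, target_size=19, stats=stats)
        assert panel.silhouette > 0.5
        assert abs(panel.silhouette - scored.silhouette) < 0.15
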