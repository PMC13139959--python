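"""Allele-sharing assignment, UPGMA, ordination, admixture EM, MLG matching."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

import panelforge as pf
from panelforge.assignment import (admixture_em, allele_sharing_distance,
                                   assign_by_sharing, frequency_assignment_test,
                                   multilocus_matches, pca, pcoa, select_k,
                                   upgma_tree, upgma_with_support)
from panelforge.core import MISSING, GenotypeMatrix, PopulationMap

from conftest import make_matrix


class TestAlleleSharing:
    def test_trivial_distances(self):
        m = make_matrix([[0, 1, 2], [0, 1, 2], [2, 1, 0]])
        d = allele_sharing_distance(m)
        assert d.iloc[0, 1] == 0.0
        assert d.iloc[0, 0] == 0.0
        # s0 vs s2: loci differ by 2,0,2 -> mean |diff|/2 = 2/3
        assert d.iloc[0, 2] == pytest.approx(2 / 3)

    def test_opposite_homozygotes_distance_one(self):
        m = make_matrix([[0] * 5, [2] * 5])
        assert allele_sharing_distance(m).iloc[0, 1] == 1.0

    def test_hom_vs_het_everywhere_is_half(self):
        m = make_matrix([[0] * 10, [1] * 10])
        assert allele_sharing_distance(m).iloc[0, 1] == 0.5

    def test_equals_complement_of_match_score(self):
        rng = np.random.default_rng(3)
        codes = rng.integers(0, 3, size=(2, 40))
        codes[rng.random(codes.shape) < 0.1] = MISSING
        m = make_matrix(codes)
        d = allele_sharing_distance(m).iloc[0, 1]
        ms = pf.match_score(codes[0], codes[1])
        assert d == pytest.approx(1 - ms / 100)

    def test_no_shared_loci_flagged(self):
        m = make_matrix([[0, MISSING], [MISSING, 2]])
        with pytest.warns(UserWarning):
            d = allele_sharing_distance(m)
        assert np.isnan(d.iloc[0, 1])


class TestAssignBySharing:
    def _setup(self):
        codes = np.array([[0] * 10, [0] * 10, [2] * 10, [2] * 10,
                          [0] * 10, [1] * 10])
        m = make_matrix(codes)
        table = pd.DataFrame({
            "sample": [f"s{i}" for i in range(6)],
            "group": ["A", "A", "B", "B", "", ""],
            "role": ["control"] * 4 + ["unknown"] * 2,
        })
        return m, PopulationMap(table)

    def test_identical_to_control_assigned(self):
        m, popmap = self._setup()
        res = {a.sample_id: a for a in assign_by_sharing(m, popmap)}
        assert res["s4"].assigned == "A"
        assert res["s4"].shared["A"] == pytest.approx(100.0)

    def test_intermediate_left_unassigned_with_top_two(self):
        m, popmap = self._setup()
        res = {a.sample_id: a for a in assign_by_sharing(m, popmap)}
        a = res["s5"]  # all-het: 50% with both groups
        assert a.assigned is None
        assert a.top_two is not None
        assert a.shared["A"] == pytest.approx(50.0)
        assert a.shared["B"] == pytest.approx(50.0)

    def test_no_controls_fatal(self):
        m = make_matrix([[0], [1]])
        popmap = PopulationMap(pd.DataFrame(
            {"sample": ["s0", "s1"], "group": ["", ""], "role": ["unknown"] * 2}))
        with pytest.raises(ValueError):
            assign_by_sharing(m, popmap)


class TestUpgma:
    def test_three_leaf_forced_topology_and_heights(self):
        d = pd.DataFrame([[0, 0.1, 0.8], [0.1, 0, 0.8], [0.8, 0.8, 0]],
                         index=list("ABC"), columns=list("ABC"))
        tree = upgma_tree(d)
        assert tree.height == pytest.approx(0.4)
        inner = [c for c in tree.children if c.children][0]
        assert sorted(inner.leaves()) == ["A", "B"]
        assert inner.height == pytest.approx(0.05)
        assert "A:" in tree.to_newick()

    def test_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(9)
        pts = rng.random((8, 3))
        d = squareform(pdist(pts))
        tree = upgma_tree(d, labels=[f"s{i}" for i in range(8)])
        z = linkage(pdist(pts), method="average")
        ours = sorted(n.height * 2 for n in tree._internal_nodes())
        scipys = sorted(z[:, 2])
        assert np.allclose(ours, scipys)
        # same nested partitions
        from scipy.cluster.hierarchy import cut_tree
        for k in (2, 3, 4):
            cuts = cut_tree(z, n_clusters=k).ravel()
            scipy_parts = {frozenset(np.where(cuts == c)[0]) for c in set(cuts)}
            heights = sorted((n.height for n in tree._internal_nodes()),
                             reverse=True)
            # cutting our tree just below the (k-1)-th largest height
            thr = heights[k - 2] - 1e-9
            parts = set()

            def collect(node):
                if node.height <= thr or not node.children:
                    parts.add(frozenset(int(l[1:]) for l in node.leaves()))
                else:
                    for c in node.children:
                        collect(c)

            collect(tree)
            assert parts == scipy_parts

    def test_tie_break_is_lexicographic_and_deterministic(self):
        d = np.array([[0, 1, 1, 2], [1, 0, 1, 2], [1, 1, 0, 2], [2, 2, 2, 0]],
                     dtype=float)
        t1 = upgma_tree(d, labels=list("ABCD"))
        t2 = upgma_tree(d, labels=list("ABCD"))
        assert t1.to_newick() == t2.to_newick()
        # among the tied unit-distance pairs, (A, B) merges first
        parts = {frozenset(n.leaves()) for n in t1._internal_nodes()}
        assert frozenset("AB") in parts

    def test_ultrametric_input_reproduced_exactly(self):
        # generating tree: ((A,B):0.2,(C,D):0.2) with heights 0.1/0.1/0.3
        d = pd.DataFrame(
            [[0, 0.2, 0.6, 0.6], [0.2, 0, 0.6, 0.6],
             [0.6, 0.6, 0, 0.2], [0.6, 0.6, 0.2, 0]],
            index=list("ABCD"), columns=list("ABCD"))
        tree = upgma_tree(d)
        parts = {frozenset(n.leaves()) for n in tree._internal_nodes()}
        assert frozenset("AB") in parts and frozenset("CD") in parts
        assert tree.height == pytest.approx(0.3)

    def test_bootstrap_supports_high_for_clean_groups(self):
        codes = np.vstack([np.zeros((3, 30)), np.full((3, 30), 2)]).astype(int)
        m = make_matrix(codes)
        tree = upgma_with_support(m, n_boot=50, seed=0)
        for node in tree._internal_nodes():
            leaves = set(node.leaves())
            if leaves in ({"s0", "s1", "s2"}, {"s3", "s4", "s5"}):
                assert node.support == pytest.approx(1.0)

    def test_missing_distance_fatal(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError):
            upgma_tree(d)


class TestOrdination:
    def test_pcoa_of_euclidean_distance_matches_pca(self):
        rng = np.random.default_rng(4)
        codes = rng.integers(0, 3, size=(12, 25))
        m = make_matrix(codes)
        coords_pca, var_pca = pca(m, n_components=3)
        d = pd.DataFrame(squareform(pdist(codes.astype(float))),
                         index=m.sample_ids, columns=m.sample_ids)
        coords_pcoa, var_pcoa = pcoa(d)
        assert np.allclose(var_pca, var_pcoa[:3], atol=1e-6)
        for k in range(3):
            r = np.corrcoef(coords_pca.iloc[:, k], coords_pcoa.iloc[:, k])[0, 1]
            assert abs(r) > 0.999

    def test_three_fixed_groups_dominate_first_axes(self):
        codes = np.vstack([np.zeros((5, 30)), np.full((5, 30), 2),
                           np.tile([0, 2], (5, 15))]).astype(int)
        m = make_matrix(codes)
        d = allele_sharing_distance(m)
        coords, var = pcoa(d)
        assert var[:2].sum() > 80

    def test_duplicated_sample_maps_to_identical_coordinates(self):
        codes = np.vstack([np.array([[0, 1, 2, 0, 1]])] * 2
                          + [np.array([[2, 1, 0, 2, 1]])]).astype(int)
        m = make_matrix(codes)
        coords, _ = pcoa(allele_sharing_distance(m))
        assert np.allclose(coords.iloc[0], coords.iloc[1], atol=1e-9)


class TestAdmixtureEM:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.integers(0, 3, size=(10, 20)))
        est = admixture_em(m, 1, seed=0)
        assert np.allclose(est.Q.to_numpy(), 1.0)
        obs = m.codes.mean(axis=0) / 2.0
        assert np.allclose(est.F.to_numpy()[0], obs, atol=1e-6)

    def test_loglik_monotone_and_q_on_simplex(self, three_pop_study):
        m = three_pop_study["genotypes"].subset(
            loci=three_pop_study["genotypes"].locus_ids[:150])
        est = admixture_em(m, 3, seed=1)
        assert np.all(np.diff(est.loglik_path) >= -1e-6)
        q = est.Q.to_numpy()
        assert np.allclose(q.sum(axis=1), 1.0)
        assert np.all(q >= 0)

    def test_pure_individuals_recovered(self, three_pop_study):
        m = three_pop_study["genotypes"].subset(
            loci=three_pop_study["genotypes"].locus_ids[:200])
        est = admixture_em(m, 3, seed=2)
        frac_confident = (est.Q.to_numpy().max(axis=1) > 0.9).mean()
        assert frac_confident >= 0.95
        assert (~est.admixed).mean() >= 0.95

    def test_balanced_admixture_recovered(self):
        cfg = pf.SimulationConfig(n_loci=1000, fst=0.5,
                                  sample_sizes=(15, 15, 15),
                                  missing_rate=0.0, seed=2)
        fr = pf.simulate_frequencies(cfg)
        m, _ = pf.simulate_genotypes(fr, cfg.sample_sizes, 0.0, seed=2)
        adm = pf.simulate_admixed([1 / 3] * 3, fr, seed=3, n_samples=3)
        mm = GenotypeMatrix(m.sample_ids + [f"adm{i}" for i in range(3)],
                            m.locus_ids, np.vstack([m.codes, adm]))
        est = admixture_em(mm, 3, seed=4)
        q_adm = est.Q.to_numpy()[-3:]
        assert np.all(np.abs(q_adm - 1 / 3) < 0.1)
        assert est.admixed.iloc[-3:].all()


class TestSelectK:
    def test_panmictic_prefers_k1(self):
        k1 = 0
        for seed in range(5):
            cfg = pf.SimulationConfig(n_populations=1, n_loci=150, fst=0.0,
                                      sample_sizes=(30,), missing_rate=0.0,
                                      seed=seed)
            fr = pf.simulate_frequencies(cfg)
            m, _ = pf.simulate_genotypes(fr, cfg.sample_sizes, 0.0, seed=seed)
            k, curve = select_k(m, k_range=range(1, 4), replicates=3, seed=seed)
            assert len(curve) == 3
            k1 += k == 1
        assert k1 >= 4  # >=80% of seeds

    def test_three_groups_select_k3(self, three_pop_study):
        m = three_pop_study["genotypes"].subset(
            loci=three_pop_study["genotypes"].locus_ids[:200])
        k, curve = select_k(m, k_range=range(1, 7), replicates=5, seed=0)
        assert k == 3
        assert list(curve["K"]) == [1, 2, 3, 4, 5, 6]


class TestMlgAndFrequencyAssignment:
    def test_all_distinct_and_one_duplicate(self):
        rng = np.random.default_rng(6)
        codes = rng.integers(0, 3, size=(6, 15))
        m = make_matrix(codes)
        unique, groups = multilocus_matches(m)
        assert unique == 6 and groups == []
        codes2 = np.vstack([codes, codes[2]])
        m2 = make_matrix(codes2)
        unique2, groups2 = multilocus_matches(m2)
        assert unique2 == 6
        assert groups2 == [["s2", "s6"]]

    def test_wildcard_mode_matches_through_missing(self):
        codes = np.array([[0, 1, 2], [0, MISSING, 2], [2, 1, 0]])
        m = make_matrix(codes)
        unique, groups = multilocus_matches(m, missing_wildcard=True)
        assert unique == 2
        assert groups == [["s0", "s1"]]

    def test_sample_from_group_frequencies_assigned(self, three_pop_study):
        m = three_pop_study["genotypes"]
        popmap = three_pop_study["popmap"]
        res = frequency_assignment_test(m, popmap).set_index("sample")
        correct = np.mean([res.loc[s, "assigned"] == popmap.group_of(s)
                           for s in m.sample_ids])
        assert correct >= 0.95

    def test_uniform_frequencies_tie_flagged(self):
        codes = np.array([[0, 1], [2, 1], [0, 1], [2, 1], [1, 1]])
        m = make_matrix(codes)
        table = pd.DataFrame({
            "sample": [f"s{i}" for i in range(5)],
            "group": ["A", "A", "B", "B", ""],
            "role": ["control"] * 4 + ["unknown"],
        })
        res = frequency_assignment_test(m, PopulationMap(table))
        assert bool(res.set_index("sample").loc["s4", "tie"])

    def test_leave_one_out_excludes_own_alleles(self):
        # control s0 carries a private allele; LOO frequencies for its own
        # group must be estimated from s1 only (floored, not 0.5)
        codes = np.array([[2], [0], [0], [0]])
        m = make_matrix(codes)
        table = pd.DataFrame({
            "sample": ["s0", "s1", "s2", "s3"],
            "group": ["A", "A", "B", "B"],
            "role": ["control"] * 4,
        })
        res = frequency_assignment_test(m, PopulationMap(table)).set_index("sample")
        # with LOO, group A frequency for s0 is floored 1/(2*1+1): loglik is
        # 2*log(1/3); without LOO it would be 2*log(1/2)
        assert res.loc["s0", "loglik_A"] == pytest.approx(2 * np.log(1 / 3))
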