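"""Ground-truth generators: Yule trees, BM traits, life-forms, coalescent."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from phylorecomb import synthetic
from phylorecomb.genewise import diversity, filter_sites, rm_hudson_kaplan
from phylorecomb.phylosignal import pic, pic_correlation
from phylorecomb.rates import build_rate_table
from phylorecomb.tree import phylo_covariance, write_newick


class TestYuleTree:
    def test_two_tips_is_cherry_with_equal_branches(self):
        tree = synthetic.yule_tree(2, 1.0, seed=0)
        tips = tree.tips()
        assert len(tips) == 2
        assert tree.branch_length[tips[0]] == pytest.approx(
            tree.branch_length[tips[1]])

    def test_same_seed_same_newick(self):
        a = write_newick(synthetic.yule_tree(20, 1.0, seed=7))
        b = write_newick(synthetic.yule_tree(20, 1.0, seed=7))
        assert a == b

    def test_ultrametric(self):
        assert synthetic.yule_tree(40, 2.0, seed=1).is_ultrametric()

    def test_mean_depth_matches_analytic_expectation(self):
        """Mean root-to-tip depth ~ sum_{k=2}^{n} 1/(k*lambda)."""
        n, lam = 20, 1.0
        expected = sum(1.0 / (k * lam) for k in range(2, n + 1))
        depths = []
        for seed in range(300):
            tree = synthetic.yule_tree(n, lam, seed=seed)
            depths.append(tree.node_depths()[tree.tips()].max())
        assert abs(np.mean(depths) - expected) / expected < 0.10

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            synthetic.yule_tree(1, 1.0, seed=0)


class TestSimulateBm:
    def test_zero_depth_tree_all_root_value(self):
        from phylorecomb.tree import parse_newick
        tree = parse_newick("(A:0,B:0,C:0);")
        trait = synthetic.simulate_bm(tree, sigma2=1.0, root_value=3.5,
                                      seed=0)
        assert all(v == pytest.approx(3.5) for v in trait.values())

    def test_tip_covariance_matches_v(self):
        """Empirical tip covariance ~ sigma^2 * V on a fixed 10-tip tree."""
        tree = synthetic.yule_tree(10, 1.0, seed=31)
        cov = phylo_covariance(tree)
        sigma2 = 2.0
        reps = 2000
        samples = np.empty((reps, 10))
        for r in range(reps):
            trait = synthetic.simulate_bm(tree, sigma2=sigma2, seed=50_000 + r)
            samples[r] = [trait[l] for l in cov.tip_labels]
        emp = np.cov(samples.T, bias=False)
        target = sigma2 * cov.V
        # 3 MC SEs per entry; var of sample covariance ~ (v_ii v_jj + v_ij^2)/n
        for i in range(10):
            for j in range(10):
                se = math.sqrt((target[i, i] * target[j, j]
                                + target[i, j] ** 2) / reps)
                assert abs(emp[i, j] - target[i, j]) <= max(3 * se, 0.05)

    def test_bivariate_correlation_recovered_via_pics(self):
        tree = synthetic.yule_tree(500, 1.0, seed=8)
        cov = np.array([[1.0, 0.8], [0.8, 1.0]])
        traits = synthetic.simulate_bm(tree, covariance=cov, seed=9,
                                       root_value=[0.0, 0.0])
        r = pic_correlation(
            pic(tree, {k: v[0] for k, v in traits.items()}),
            pic(tree, {k: v[1] for k, v in traits.items()}))
        assert 0.7 <= r <= 0.9

    def test_non_psd_covariance_rejected(self):
        tree = synthetic.yule_tree(5, 1.0, seed=0)
        with pytest.raises(ValueError):
            synthetic.simulate_bm(tree, covariance=[[1, 2], [2, 1]], seed=0)


class TestAssignLifeForms:
    def test_zero_switch_rate_inherits_root_state(self):
        tree = synthetic.yule_tree(30, 1.0, seed=3)
        state, _ = synthetic.assign_life_forms(tree, switch_rate=0.0,
                                               seed=0, root_state="shrub")
        assert set(state.values()) == {"shrub"}

    def test_seeded_reproducibility(self):
        tree = synthetic.yule_tree(30, 1.0, seed=3)
        s1, _ = synthetic.assign_life_forms(tree, switch_rate=1.0, seed=4)
        s2, _ = synthetic.assign_life_forms(tree, switch_rate=1.0, seed=4)
        assert s1 == s2

    def test_clade_painting_with_effect(self):
        tree = synthetic.yule_tree(20, 1.0, seed=5)
        # paint the subtree under the first internal child as conifers
        internal = next(c for c in tree.children[tree.root]
                        if tree.children[c])
        tree.labels[internal] = "cladeX"
        base = {l: 0.0 for l in tree.tip_labels}
        state, trait = synthetic.assign_life_forms(
            tree, levels=("tree", "conifer tree"), clades={"cladeX": "conifer tree"},
            base_trait=base, group_effects={"conifer tree": -1.1},
            seed=0, root_state="tree")
        painted = [l for l, s in state.items() if s == "conifer tree"]
        assert painted
        for l in painted:
            assert trait[l] == pytest.approx(-1.1)
        for l in set(base) - set(painted):
            assert trait[l] == pytest.approx(0.0)

    def test_high_switch_rate_near_uniform(self):
        """At fast switching the stationary distribution is uniform."""
        tree = synthetic.yule_tree(300, 1.0, seed=6)
        state, _ = synthetic.assign_life_forms(
            tree, levels=("herb", "shrub", "tree"), switch_rate=50.0, seed=7)
        counts = np.array([sum(1 for s in state.values() if s == lvl)
                           for lvl in ("herb", "shrub", "tree")])
        assert sps.chisquare(counts).pvalue > 0.001

    def test_empty_levels_rejected(self):
        tree = synthetic.yule_tree(5, 1.0, seed=0)
        with pytest.raises(ValueError):
            synthetic.assign_life_forms(tree, levels=())


class TestCoalescentWithRecombination:
    def test_no_recombination_means_rm_zero(self):
        for seed in range(30):
            aln = synthetic.coalescent_with_recombination(
                12, 8.0, 0.0, 800, seed=seed)
            snp = filter_sites(aln, informative_only=False)
            assert rm_hudson_kaplan(snp) == 0

    def test_pairwise_differences_match_theta_for_two_samples(self):
        """E[pi] = theta for n = 2."""
        theta = 5.0
        diffs = []
        for seed in range(800):
            aln = synthetic.coalescent_with_recombination(
                2, theta, 0.0, 5000, seed=seed)
            diffs.append(int(np.sum(aln.seqs[0] != aln.seqs[1])))
        se = np.std(diffs) / math.sqrt(len(diffs))
        assert abs(np.mean(diffs) - theta) <= 3 * se

    def test_segregating_sites_match_watterson(self):
        """Mean S ~ theta * a_{n-1} at rho = 0 (small-n version)."""
        n, theta = 10, 5.0
        expected = theta * sum(1.0 / i for i in range(1, n))
        s_vals = []
        for seed in range(500):
            aln = synthetic.coalescent_with_recombination(
                n, theta, 0.0, 4000, seed=seed)
            s_vals.append(filter_sites(aln, informative_only=False).s)
        se = np.std(s_vals) / math.sqrt(len(s_vals))
        assert abs(np.mean(s_vals) - expected) <= 3 * se

    def test_matches_msprime_sfs_distribution(self):
        """S distributions agree with an independent coalescent simulator
        at matched parameters (KS test), with recombination active."""
        msprime = pytest.importorskip("msprime")
        n, theta, rho = 10, 5.0, 5.0
        ours = []
        for seed in range(300):
            aln = synthetic.coalescent_with_recombination(
                n, theta, rho, 4000, seed=seed)
            ours.append(filter_sites(aln, informative_only=False).s)
        theirs = []
        # ploidy 1, N = 1: pairwise coalescence rate 1/N = 1, matching our
        # time scale; recombination rho/2 and mutation theta/2 per unit time
        reps = msprime.sim_ancestry(
            samples=n, ploidy=1, population_size=1.0, sequence_length=1.0,
            recombination_rate=rho / 2.0, discrete_genome=False,
            num_replicates=300, random_seed=1234)
        for i, ts in enumerate(reps):
            mts = msprime.sim_mutations(ts, rate=theta / 2.0,
                                        discrete_genome=False,
                                        random_seed=10_000 + i)
            theirs.append(mts.num_sites)
        assert sps.ks_2samp(ours, theirs).pvalue > 0.01

    def test_determinism(self):
        a = synthetic.coalescent_with_recombination(8, 5.0, 3.0, 500, seed=2)
        b = synthetic.coalescent_with_recombination(8, 5.0, 3.0, 500, seed=2)
        assert np.array_equal(a.seqs, b.seqs)


class TestSpeciesTableFixture:
    def test_roundtrip_exact(self):
        tree = synthetic.yule_tree(40, 1.0, seed=15)
        records, truth = synthetic.species_table_fixture(tree, seed=16)
        table, excl = build_rate_table(records)
        assert excl.empty
        latent = {r["species"]: r["log_rate"] for r in truth["rows"]}
        for _, row in table.iterrows():
            assert row["log_rate"] == pytest.approx(
                latent[row["species"]], abs=1e-9)

    def test_degenerate_parameters_give_constant_rate(self):
        tree = synthetic.yule_tree(10, 1.0, seed=17)
        records, truth = synthetic.species_table_fixture(
            tree, slope_he=0.0, intercept=-1.0,
            group_effects={}, noise_sigma2=0.0, seed=18)
        table, _ = build_rate_table(records)
        np.testing.assert_allclose(table["log_rate"], -1.0, atol=1e-9)

    def test_conifer_clade_painting(self):
        tree = synthetic.yule_tree(30, 1.0, seed=19)
        internal = next(c for c in tree.children[tree.root]
                        if tree.children[c])
        tree.labels[internal] = "conif"
        records, truth = synthetic.species_table_fixture(
            tree, seed=20, conifer_clade="conif")
        conifers = [r for r in records if r.taxon_group == "conifer"]
        assert conifers and all(r.life_form == "tree" for r in conifers)
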