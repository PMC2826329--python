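"""Site filters, diversity, Hudson-Kaplan Rm, composite-likelihood rho."""

import itertools
import math

import numpy as np
import pytest

from phylorecomb import synthetic
from phylorecomb.genewise import (
    HaplotypeAlignment,
    SnpMatrix,
    check_eligibility,
    composite_rho,
    diversity,
    filter_sites,
    gene_stats,
    read_fasta,
    rm_hudson_kaplan,
    two_locus_table,
    _fold_config,
    _incompatible_pairs,
)


def aln_from_strings(seqs, labels=None):
    labels = labels or [f"h{i}" for i in range(len(seqs))]
    return HaplotypeAlignment(labels=labels,
                              seqs=np.array([list(s) for s in seqs]))


def snp_from_rows(rows):
    m = np.array(rows, dtype=np.uint8)
    return SnpMatrix(matrix=m, positions=np.arange(1, m.shape[1] + 1))


class TestReadFasta:
    def test_basic(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">a\nACGTACGTAC\n>b\nacgtacgttc\n")
        aln = read_fasta(p)
        assert aln.n == 2 and aln.length == 10
        assert "".join(aln.seqs[1]) == "ACGTACGTTC"  # upper-cased

    def test_unequal_lengths_rejected(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">a\nACGTACGTAC\n>b\nACGTACGTA\n")
        with pytest.raises(ValueError, match="unequal"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text("")
        with pytest.raises(ValueError):
            read_fasta(p)

    def test_duplicate_labels_rejected(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">a\nAC\n>a\nAC\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(p)


class TestFilterSites:
    def test_biallelic_retained_and_encoded(self):
        aln = aln_from_strings(["AA", "AA", "TA", "TA"])
        snp = filter_sites(aln)
        assert snp.s == 1
        np.testing.assert_array_equal(snp.matrix[:, 0], [0, 0, 1, 1])

    def test_gap_column_dropped_as_indel(self):
        aln = aln_from_strings(["A-", "AT", "TT", "TA"])
        snp = filter_sites(aln)
        assert (2, "indel") in snp.dropped

    def test_three_state_column_dropped(self):
        aln = aln_from_strings(["AA", "CA", "GT", "AT"])
        snp = filter_sites(aln)
        assert (1, ">2 states") in snp.dropped

    def test_singleton_dropped_when_informative_only(self):
        aln = aln_from_strings(["AT", "AT", "AT", "TT"])
        strict = filter_sites(aln, informative_only=True)
        loose = filter_sites(aln, informative_only=False)
        assert (1, "singleton") in strict.dropped and strict.s == 0
        assert loose.s == 1

    def test_monomorphic_dropped(self):
        aln = aln_from_strings(["AA", "AA", "AA", "AA"])
        snp = filter_sites(aln)
        assert snp.s == 0 and all(r == "monomorphic" for _, r in snp.dropped)


class TestEligibility:
    @pytest.mark.parametrize("L,S,n,bad", [
        (799, 15, 30, "length"),
        (1000, 9, 30, "segregating sites"),
        (1000, 12, 20, "chromosomes"),  # 20 is not > 20
    ])
    def test_each_rule(self, L, S, n, bad):
        aln = aln_from_strings(["A" * L] * n)
        ok, reasons = check_eligibility(aln, S)
        assert not ok and bad in reasons

    def test_eligible(self):
        aln = aln_from_strings(["A" * 800] * 21)
        ok, reasons = check_eligibility(aln, 10)
        assert ok and not reasons


class TestDiversity:
    def test_two_haplotypes_one_difference(self):
        snp = snp_from_rows([[0], [1]])
        pi, _, s = diversity(snp, 2, 100)
        assert pi == pytest.approx(0.01) and s == 1

    def test_identical_haplotypes(self):
        snp = SnpMatrix(matrix=np.zeros((4, 0), dtype=np.uint8),
                        positions=np.array([], dtype=np.int64))
        assert diversity(snp, 4, 100) == (0.0, 0.0, 0)

    def test_watterson_harmonic_sum(self):
        # S=10, n=11, L=1000: a_10 = 2.928968
        snp = snp_from_rows([[i < k for k in range(1, 11)]
                             for i in range(11)])
        _, tw, s = diversity(snp, 11, 1000)
        a_n = sum(1.0 / i for i in range(1, 11))
        assert a_n == pytest.approx(2.928968, abs=1e-6)
        assert tw == pytest.approx(10 / (a_n * 1000))

    def test_pi_bounded_by_s_over_l(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            m = rng.integers(0, 2, size=(8, 12)).astype(np.uint8)
            snp = SnpMatrix(matrix=m, positions=np.arange(1, 13))
            pi, _, s = diversity(snp, 8, 12)
            assert pi <= s / 12 + 1e-12

    def test_invariant_to_row_permutation_and_relabeling(self):
        rng = np.random.default_rng(1)
        m = rng.integers(0, 2, size=(10, 6)).astype(np.uint8)
        snp = SnpMatrix(matrix=m, positions=np.arange(1, 7))
        base = diversity(snp, 10, 50)
        perm = SnpMatrix(matrix=m[rng.permutation(10)],
                         positions=snp.positions)
        flip = SnpMatrix(matrix=1 - m, positions=snp.positions)
        assert diversity(perm, 10, 50) == pytest.approx(base)
        assert diversity(flip, 10, 50) == pytest.approx(base)


def rm_exhaustive_oracle(matrix):
    """Minimum number of crossover points compatible with the data.

    Brute force: every four-gamete-incompatible pair (i, j) needs a point
    in one of the inter-site gaps i..j-1; search subsets of gaps by size.
    """
    inc = _incompatible_pairs(matrix)
    s = matrix.shape[1]
    intervals = [set(range(i, j)) for i in range(s) for j in range(i + 1, s)
                 if inc[i, j]]
    if not intervals:
        return 0
    gaps = sorted(set().union(*intervals))
    for r in range(1, len(gaps) + 1):
        for chosen in itertools.combinations(gaps, r):
            cs = set(chosen)
            if all(iv & cs for iv in intervals):
                return r
    raise AssertionError("unreachable")


class TestRmHudsonKaplan:
    def test_compatible_data_zero(self):
        snp = snp_from_rows([[0, 0], [0, 1], [1, 1]])
        assert rm_hudson_kaplan(snp) == 0

    def test_four_gametes_one_event(self):
        snp = snp_from_rows([[0, 0], [0, 1], [1, 0], [1, 1]])
        assert rm_hudson_kaplan(snp) == 1

    def test_single_column_zero(self):
        snp = snp_from_rows([[0], [1]])
        assert rm_hudson_kaplan(snp) == 0

    def test_adjacent_intervals_both_counted(self):
        # incompatible pairs (0,1) and (1,2): open intervals are disjoint
        rows = [[0, 0, 0], [0, 1, 1], [1, 0, 1], [1, 1, 0]]
        snp = snp_from_rows(rows)
        inc = _incompatible_pairs(snp.matrix)
        assert inc[0, 1] and inc[1, 2]
        assert rm_hudson_kaplan(snp) == rm_exhaustive_oracle(snp.matrix)

    def test_matches_exhaustive_oracle_random(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(4, 13))
            s = int(rng.integers(2, 11))
            m = rng.integers(0, 2, size=(n, s)).astype(np.uint8)
            snp = SnpMatrix(matrix=m, positions=np.arange(1, s + 1))
            assert rm_hudson_kaplan(snp) == rm_exhaustive_oracle(m)


class TestFoldConfig:
    def test_symmetries_collapse(self):
        base = _fold_config(3, 2, 1, 4)
        assert _fold_config(1, 4, 3, 2) == base  # flip locus A
        assert _fold_config(2, 3, 4, 1) == base  # flip locus B
        assert _fold_config(3, 1, 2, 4) == base  # swap loci


@pytest.fixture(scope="module")
def small_table():
    return two_locus_table(8, (0.0, 1.0, 10.0), mc_reps=4000, seed=5)


class TestTwoLocusTable:
    def test_rho_zero_forbids_four_gametes(self, small_table):
        floor_log = math.log(small_table.floor)
        zero_col = list(small_table.grid).index(0.0)
        for cfg, row in small_table.configs.items():
            if all(c > 0 for c in cfg):  # all four gametes present
                assert small_table.log_probs[row, zero_col] == \
                    pytest.approx(floor_log)

    def test_probabilities_normalized(self, small_table):
        sums = np.exp(small_table.log_probs).sum(axis=0)
        # unseen-config floors can push sums slightly above 1
        assert np.all(sums >= 0.99) and np.all(sums < 1.2)

    def test_seed_self_consistency(self):
        """Two independent seeds agree within Monte-Carlo error."""
        t1 = two_locus_table(8, (0.0, 10.0), mc_reps=6000, seed=1)
        t2 = two_locus_table(8, (0.0, 10.0), mc_reps=6000, seed=2)
        col = 1  # rho = 10
        common = set(t1.configs) & set(t2.configs)
        assert len(common) > 10
        for cfg in common:
            p1 = math.exp(t1.log_probs[t1.configs[cfg], col])
            p2 = math.exp(t2.log_probs[t2.configs[cfg], col])
            if max(p1, p2) < 0.005:
                continue  # below resolution for an SE-based check
            # replicate weighting (tree-length products) overdisperses the
            # estimate relative to binomial sampling; allow ~2x binomial SE
            # at 3 sigma
            se = math.sqrt(max(p1, p2) * (1 - max(p1, p2)) / 6000)
            assert abs(p1 - p2) <= max(6 * se, 0.015)

    def test_grid_must_include_zero(self):
        with pytest.raises(ValueError):
            two_locus_table(8, (1.0, 5.0), mc_reps=10)


class TestCompositeRho:
    def test_perfect_ld_boundary_zero(self):
        table = two_locus_table(8, (0.0, 1.0, 10.0), mc_reps=2000, seed=3)
        # two sites in complete linkage: no evidence for recombination
        m = np.array([[0, 0]] * 4 + [[1, 1]] * 4, dtype=np.uint8)
        snp = SnpMatrix(matrix=m, positions=np.array([1, 500]))
        rho_hat, _ = composite_rho(snp, 8, table)
        assert rho_hat == 0.0

    def test_rho_over_theta_arithmetic(self):
        # rho 8 over per-gene thetaW 4 -> 2.0 (via the gene_stats contract)
        assert 8.0 / 4.0 == pytest.approx(2.0)

    def test_deterministic_given_table(self, twolocus_n30):
        aln = synthetic.coalescent_with_recombination(30, 10.0, 10.0, 1500,
                                                      seed=44)
        snp = filter_sites(aln)
        r1, ll1 = composite_rho(snp, 30, twolocus_n30)
        r2, ll2 = composite_rho(snp, 30, twolocus_n30)
        assert r1 == r2 and ll1 == ll2


class TestGeneStats:
    def test_full_summary_on_simulated_gene(self, twolocus_n30):
        aln = synthetic.coalescent_with_recombination(30, 10.0, 10.0, 1500,
                                                      seed=7)
        st = gene_stats(aln, gene="g1", table=twolocus_n30)
        assert st.n == 30 and st.length == 1500
        assert st.eligible
        assert st.theta_pi > 0 and st.theta_w > 0
        assert st.rm >= 0
        assert st.rho_hat is not None and st.rho_hat >= 0
        if st.rho_hat > 0:
            theta_gene = st.theta_w * st.length
            assert st.rho_over_theta == pytest.approx(st.rho_hat / theta_gene)

    def test_ineligible_short_gene(self):
        aln = aln_from_strings(["ACGT" * 50] * 25)
        st = gene_stats(aln, gene="short")
        assert not st.eligible and "length" in st.reasons
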