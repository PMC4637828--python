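import numpy as np
import pytest

from migranet.datamodel import DNAProfile, HaplotypeSet
from migranet.popgen import (
    DistanceMatrix,
    amova,
    exact_g_test_mcmc,
    haplotype_and_nucleotide_diversity,
    josts_d,
    locus_summary,
    multilocus_phi_st,
    pairwise_fst_mtdna,
    permutation_pvalue,
    sequence_distance_matrix,
    weir_cockerham_fst,
)


def _profile(sid, pop, geno):
    return DNAProfile(sid, pop, "calving", pop, genotype=geno)


class TestDiversity:
    def test_unbiased_haplotype_diversity(self):
        dm = DistanceMatrix.identity(["A", "B", "C"])
        h, _ = haplotype_and_nucleotide_diversity({"A": 2, "B": 1, "C": 1}, dm)
        assert h == pytest.approx(5 / 6)  # n(1-Σp²)/(n-1) = 4(1-0.375)/3

    def test_single_haplotype(self):
        dm = DistanceMatrix.identity(["A"])
        h, pi = haplotype_and_nucleotide_diversity({"A": 5}, dm)
        assert h == 0.0 and pi == 0.0

    def test_two_sequences_five_diffs_per_site(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0.0, 5.0], [5.0, 0.0]]))
        _, pi = haplotype_and_nucleotide_diversity({"A": 1, "B": 1}, dm, seq_length=500)
        assert pi == pytest.approx(0.01)

    def test_fewer_than_two_sequences_rejected(self):
        dm = DistanceMatrix.identity(["A"])
        with pytest.raises(ValueError):
            haplotype_and_nucleotide_diversity({"A": 1}, dm)


class TestLocusSummary:
    def test_monomorphic(self):
        pro = [_profile(f"s{i}", "X", {"L1": (100, 100)}) for i in range(5)]
        (s,) = locus_summary(pro)
        assert (s.n_alleles, s.ho, s.he) == (1, 0.0, 0.0)

    def test_all_heterozygotes_small_sample_correction(self):
        pro = [_profile(f"s{i}", "X", {"L1": (100, 102)}) for i in range(10)]
        (s,) = locus_summary(pro)
        assert s.ho == 1.0
        assert s.he == pytest.approx(20 / 19 * 0.5)

    def test_against_brute_force_tabulation(self):
        rng = np.random.default_rng(0)
        pro = [
            _profile(f"s{i}", "X", {"L1": tuple(sorted(rng.integers(1, 5, 2)))})
            for i in range(40)
        ]
        (s,) = locus_summary(pro)
        pairs = [p.genotype["L1"] for p in pro]
        alleles = [a for pr in pairs for a in pr]
        freqs = np.array([alleles.count(a) / len(alleles) for a in sorted(set(alleles))])
        ho = sum(a != b for a, b in pairs) / len(pairs)
        he = len(alleles) / (len(alleles) - 1) * (1 - (freqs**2).sum())
        assert s.ho == pytest.approx(ho) and s.he == pytest.approx(he)


class TestSequenceDistances:
    def test_known_differences(self, toy_hapset):
        dm = sequence_distance_matrix(toy_hapset)
        assert dm.value("HapA", "HapB") == 1
        assert dm.value("HapA", "HapC") == 2
        assert dm.value("HapB", "HapC") == 1

    def test_n_sites_skipped(self):
        hs = HaplotypeSet({"a": "ACGTN", "b": "ACGAA", "c": "ACGTA"})
        dm = sequence_distance_matrix(hs)
        assert dm.value("a", "b") == 1  # last site masked by N
        assert dm.value("a", "c") == 0

    def test_symmetry_zero_diagonal_random(self):
        rng = np.random.default_rng(1)
        seqs = {
            f"h{i}": "".join(rng.choice(list("ACGT"), 50)) for i in range(6)
        }
        dm = sequence_distance_matrix(HaplotypeSet(seqs))
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.all(np.diag(dm.matrix) == 0)
        assert dm.matrix.max() <= 50


class TestAMOVA:
    def test_fixed_difference_phi_is_one(self):
        res = amova(["A"] * 5 + ["B"] * 5, ["h1"] * 5 + ["h2"] * 5)
        assert res.phi_st == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self):
        labels = ["A", "B"] * 100
        haps = (["h1"] * 2 + ["h2"] * 2) * 50
        res = amova(labels, haps)
        assert abs(res.phi_st) < 0.05

    def test_sums_of_squares_decompose_total(self):
        rng = np.random.default_rng(2)
        labels = list(rng.choice(["A", "B", "C"], 40))
        haps = list(rng.choice(["h1", "h2", "h3"], 40))
        dm = DistanceMatrix(
            ("h1", "h2", "h3"),
            np.array([[0, 3, 5], [3, 0, 4], [5, 4, 0]], dtype=float),
        )
        res = amova(labels, haps, dm)
        hidx = {h: i for i, h in enumerate(dm.labels)}
        d2 = dm.matrix[np.ix_([hidx[h] for h in haps], [hidx[h] for h in haps])]
        ss_total = d2.sum() / (2 * 40)
        assert sum(res.ss) == pytest.approx(ss_total)
        assert sum(res.df) == 39
        assert res.total_variance == pytest.approx(res.sigma_among + res.sigma_within)

    def test_identity_distance_equals_frequency_fst(self):
        rng = np.random.default_rng(3)
        labels = list(rng.choice(["A", "B", "C"], 60))
        haps = list(rng.choice(["h1", "h2", "h3", "h4"], 60))
        res_default = amova(labels, haps, None)
        res_explicit = amova(labels, haps, DistanceMatrix.identity(["h1", "h2", "h3", "h4"]))
        assert res_default.phi_st == pytest.approx(res_explicit.phi_st, abs=1e-12)

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            amova(["A"] * 4, ["h1"] * 4)

    def test_three_level_decomposition_consistency(self):
        rng = np.random.default_rng(4)
        pops = ["P1"] * 15 + ["P2"] * 15 + ["P3"] * 15 + ["P4"] * 15
        haps = list(rng.choice(["h1", "h2", "h3"], 60))
        groups = {"P1": "G1", "P2": "G1", "P3": "G2", "P4": "G2"}
        res = amova(pops, haps, None, groups=groups)
        assert sum(res.df) == 59
        assert res.phi_st == pytest.approx(
            (res.sigma_among_groups + res.sigma_among) / res.total_variance
        )


class TestWeirCockerham:
    def test_fixed_difference_is_one(self):
        a = [_profile(f"a{i}", "A", {"L1": (100, 100)}) for i in range(10)]
        b = [_profile(f"b{i}", "B", {"L1": (102, 102)}) for i in range(10)]
        assert weir_cockerham_fst(a + b).estimate == pytest.approx(1.0)

    def test_random_split_near_zero(self, island_sim_null):
        _, profiles, _ = island_sim_null
        assert abs(weir_cockerham_fst(profiles).estimate) < 0.01

    def test_matches_independent_anova_oracle(self):
        """WC84 closed formulas vs an independent ANOVA-sums-of-squares route."""

        def oracle(genotypes_by_pop):
            pops = [g for g in genotypes_by_pop if g]
            r = len(pops)
            n = np.array([len(g) for g in pops], float)
            N = n.sum()
            nc = (N - (n**2).sum() / N) / (r - 1)
            alleles = sorted({a for g in pops for pair in g for a in pair})
            tot_a = tot_all = 0.0
            for al in alleles:
                x = [np.array([pair.count(al) for pair in g], float) for g in pops]
                pk = np.array([xi.mean() / 2 for xi in x])
                pbar = (n * pk).sum() / N
                msg = sum(pair.count(al) == 1 for g in pops for pair in g) / (2 * N)
                msi = sum(
                    (2 * (xi / 2 - pki) ** 2).sum() for xi, pki in zip(x, pk)
                ) / (N - r)
                msp = (2 * n * (pk - pbar) ** 2).sum() / (r - 1)
                a = (msp - msi) / (2 * nc)
                b = (msi - msg) / 2
                c = msg
                tot_a += a
                tot_all += a + b + c
            return tot_a / tot_all

        rng = np.random.default_rng(5)
        for _ in range(5):
            by_pop = [
                [tuple(sorted(rng.integers(1, 5, 2))) for _ in range(int(rng.integers(5, 15)))]
                for _ in range(3)
            ]
            pro = [
                _profile(f"p{k}_{i}", f"P{k}", {"L1": g})
                for k, pop in enumerate(by_pop)
                for i, g in enumerate(pop)
            ]
            mine = weir_cockerham_fst(pro).estimate
            assert mine == pytest.approx(oracle(by_pop), abs=1e-12)

    def test_relabeling_and_stratum_order_invariance(self, island_sim_f10):
        _, profiles, _ = island_sim_f10
        base = weir_cockerham_fst(profiles).estimate
        shifted = [
            DNAProfile(
                p.sample_id, p.location, p.habitat, p.management_unit, p.sex, p.haplotype,
                {l: (a + 40, b + 40) for l, (a, b) in p.genotype.items()},
            )
            for p in profiles
        ]
        assert weir_cockerham_fst(shifted).estimate == pytest.approx(base, abs=1e-12)
        assert weir_cockerham_fst(list(reversed(profiles))).estimate == pytest.approx(base, abs=1e-12)

    def test_all_monomorphic_flagged_nan(self):
        a = [_profile(f"a{i}", "A", {"L1": (100, 100)}) for i in range(5)]
        b = [_profile(f"b{i}", "B", {"L1": (100, 100)}) for i in range(5)]
        assert np.isnan(weir_cockerham_fst(a + b).estimate)


class TestJostsD:
    def test_fixed_difference_is_one(self):
        a = [_profile(f"a{i}", "A", {"L1": (100, 100)}) for i in range(10)]
        b = [_profile(f"b{i}", "B", {"L1": (102, 102)}) for i in range(10)]
        assert josts_d(a + b).estimate == pytest.approx(1.0)

    def test_null_envelope(self, island_sim_null):
        _, profiles, _ = island_sim_null
        assert abs(josts_d(profiles).estimate) < 0.02

    def test_monomorphic_is_zero(self):
        a = [_profile(f"a{i}", "A", {"L1": (100, 100)}) for i in range(5)]
        b = [_profile(f"b{i}", "B", {"L1": (100, 100)}) for i in range(5)]
        assert josts_d(a + b).estimate == 0.0


class TestPermutation:
    def test_observed_below_all_permuted(self):
        # constant statistic yields p = 1 under the add-one rule
        _, p = permutation_pvalue(lambda lab: 0.0, ["a", "b"] * 10, n_perm=99, seed=0)
        assert p == 1.0

    def test_observed_above_all_permuted_formula(self):
        calls = {"n": 0}

        def stat(lab):
            calls["n"] += 1
            return 1.0 if calls["n"] == 1 else 0.0

        _, p = permutation_pvalue(stat, ["a", "b"] * 10, n_perm=9999, seed=0)
        assert p == pytest.approx(1 / 10000)

    def test_pairwise_mtdna_fixed_difference(self, toy_hapset):
        labels = ["X"] * 6 + ["Y"] * 6
        haps = ["HapA"] * 6 + ["HapC"] * 6
        dm = sequence_distance_matrix(toy_hapset)
        fst, phist = pairwise_fst_mtdna(labels, haps, dm, n_perm=199, seed=0)
        assert fst.estimate == pytest.approx(1.0)
        assert phist.estimate == pytest.approx(1.0)
        assert fst.p_value <= 0.05 and phist.p_value <= 0.05

    def test_identical_strata_null(self, toy_hapset):
        labels = ["X", "Y"] * 20
        haps = (["HapA", "HapA", "HapB", "HapB"]) * 10
        dm = sequence_distance_matrix(toy_hapset)
        fst, phist = pairwise_fst_mtdna(labels, haps, dm, n_perm=199, seed=1)
        assert abs(fst.estimate) < 0.1 and fst.p_value > 0.2


class TestExactGTest:
    def test_agrees_with_fisher_2x2(self):
        from scipy import stats

        for seed, tbl in enumerate([[[8, 2], [1, 5]], [[3, 7], [9, 2]], [[5, 5], [6, 4]]]):
            p, se = exact_g_test_mcmc(tbl, n_steps=100_000, n_dememorization=5_000, seed=seed)
            fisher = stats.fisher_exact(tbl).pvalue
            assert abs(p - fisher) <= 3 * max(se, 1e-3)

    def test_identical_columns_large_n(self):
        p, _ = exact_g_test_mcmc([[50, 50], [50, 50]], n_steps=20_000, n_dememorization=2_000, seed=3)
        assert p > 0.5

    def test_label_permutation_invariance(self):
        tbl = [[8, 2, 4], [1, 5, 3]]
        swapped = [[2, 8, 4], [5, 1, 3]]
        p1, se1 = exact_g_test_mcmc(tbl, n_steps=60_000, n_dememorization=5_000, seed=4)
        p2, se2 = exact_g_test_mcmc(swapped, n_steps=60_000, n_dememorization=5_000, seed=5)
        assert abs(p1 - p2) <= 3 * (se1 + se2)

    def test_degenerate_margins(self):
        assert exact_g_test_mcmc([[5, 0], [3, 0]], n_steps=100, seed=0)[0] == 1.0


class TestMultilocusAMOVA:
    def test_component_summation_matches_single_locus(self):
        labels = ["A"] * 5 + ["B"] * 5
        haps = ["h1"] * 5 + ["h2"] * 5
        res = amova(labels, haps)
        assert multilocus_phi_st([res, res]) == pytest.approx(res.phi_st)
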