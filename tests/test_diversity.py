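"""Diversity statistics, rarefaction, resampling tests, BY correction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ssrtrace.diversity import (
    by_correction,
    evanno_delta_k,
    expected_het,
    fis,
    hwe_test,
    he_permutation_test,
    ld_test,
    mean_expected_het,
    observed_het,
    paired_he_comparison,
    private_alleles,
    rarefied_allelic_richness,
)
from ssrtrace.genotype_io import MISSING, GenotypeMatrix, allele_frequencies


class TestExpectedHet:
    def test_monomorphic_is_zero(self):
        assert expected_het([1.0], 50) == 0.0

    def test_unbiased_factor(self):
        # (10/9) * (1 - 0.5) = 0.5556
        assert expected_het([0.5, 0.5], 10) == pytest.approx(0.55556, abs=1e-4)

    def test_permutation_invariance(self):
        p = [0.5, 0.3, 0.2]
        assert expected_het(p, 20) == pytest.approx(expected_het(p[::-1], 20))

    def test_gene_count_guard(self):
        with pytest.raises(ValueError):
            expected_het([0.5, 0.5], 1)

    def test_unbiasedness_under_resampling(self):
        # mean of the estimator over multinomial resamples approaches the
        # population gene diversity
        rng = np.random.default_rng(11)
        p = np.array([0.4, 0.3, 0.2, 0.1])
        truth = 1 - (p**2).sum()
        n = 20
        vals = []
        for _ in range(10000):
            counts = rng.multinomial(n, p)
            vals.append(expected_het(counts / n, n))
        assert np.mean(vals) == pytest.approx(truth, abs=0.01)


def test_observed_het_direct_count():
    calls = np.array([[[1, 2]], [[1, 1]]], dtype=np.int64)
    g = GenotypeMatrix(["a", "b"], ["L1"], calls, np.array(["P", "P"], dtype=object))
    assert observed_het(g, "L1", "P") == 0.5


def test_observed_het_matches_brute_force():
    rng = np.random.default_rng(3)
    calls = rng.integers(1, 4, size=(40, 2, 2))
    calls[rng.random((40, 2)) < 0.15] = MISSING
    g = GenotypeMatrix(
        [f"i{k}" for k in range(40)], ["L1", "L2"], calls,
        np.array(["P"] * 40, dtype=object),
    )
    for j, locus in enumerate(g.loci):
        cell = calls[:, j, :]
        ok = cell[:, 0] != MISSING
        expected = np.mean([a != b for a, b in cell[ok]])
        assert observed_het(g, locus, "P") == pytest.approx(expected)


class TestFis:
    def test_panmixia(self):
        assert fis(0.5, 0.5) == 0.0

    def test_full_inbreeding(self):
        assert fis(0.0, 0.7) == 1.0

    def test_reported_mainland_value(self):
        assert fis(0.291, 0.794) == pytest.approx(0.634, abs=5e-4)
        assert fis(0.291, 0.765) == pytest.approx(0.620, abs=5e-3)

    def test_monomorphic_flagged(self):
        assert np.isnan(fis(0.0, 0.0))


class TestRarefaction:
    def test_full_sample_gives_observed_count(self):
        assert rarefied_allelic_richness([3, 2, 1], 6) == pytest.approx(3.0)

    def test_single_gene_limit(self):
        assert rarefied_allelic_richness([4, 4], 1) == pytest.approx(1.0)

    def test_exhaustive_enumeration_all_small_cases(self):
        # oracle: average distinct-allele count over every C(N, g) subsample
        def oracle(counts, g):
            genes = [i for i, c in enumerate(counts) for _ in range(c)]
            subs = list(itertools.combinations(genes, g))
            return np.mean([len(set(s)) for s in subs])

        cases = [(1, 2, 3), (4, 4), (2, 2, 2, 2), (1, 1, 1, 1, 1, 1), (5, 3), (8,)]
        for counts in cases:
            N = sum(counts)
            assert N <= 8
            for g in range(1, N + 1):
                assert rarefied_allelic_richness(counts, g) == pytest.approx(
                    oracle(counts, g), abs=1e-10
                )

    def test_oversized_subsample_rejected(self):
        with pytest.raises(ValueError):
            rarefied_allelic_richness([2, 2], 5)


class TestPrivateAlleles:
    def test_shared_not_private_and_disjoint_all_private(self):
        calls = np.array(
            [[[1, 2]], [[1, 1]], [[3, 4]], [[4, 4]]], dtype=np.int64
        )
        pops = np.array(["A", "A", "B", "B"], dtype=object)
        g = GenotypeMatrix(list("abcd"), ["L1"], calls, pops)
        t = allele_frequencies(g)
        pa = private_alleles(t)
        assert pa == {"A": 2, "B": 2}  # disjoint supports

    def test_brute_force_set_difference(self):
        rng = np.random.default_rng(9)
        calls = rng.integers(1, 8, size=(60, 3, 2))
        pops = np.array(["A"] * 20 + ["B"] * 20 + ["C"] * 20, dtype=object)
        g = GenotypeMatrix([f"i{k}" for k in range(60)], ["L1", "L2", "L3"], calls, pops)
        t = allele_frequencies(g)
        pa = private_alleles(t)
        for pop in "ABC":
            count = 0
            for j, locus in enumerate(g.loci):
                mine = set(calls[pops == pop, j, :].ravel())
                others = set(calls[pops != pop, j, :].ravel())
                count += len(mine - others)
            assert pa[pop] == count


class TestHweTest:
    def test_hwe_data_large_p(self, hwe_population):
        res = hwe_test(hwe_population, "L1", "pop", n_mc=400, seed=5)
        assert res.p_value > 0.2

    def test_all_heterozygotes_rejected(self):
        calls = np.tile(np.array([[1, 2]], dtype=np.int64), (50, 1, 1)).reshape(50, 1, 2)
        g = GenotypeMatrix(
            [f"i{k}" for k in range(50)], ["L1"], calls,
            np.array(["P"] * 50, dtype=object),
        )
        res = hwe_test(g, "L1", "P", n_mc=400, seed=5)
        assert res.p_value < 0.05

    def test_monomorphic_is_na(self):
        calls = np.full((10, 1, 2), 7, dtype=np.int64)
        g = GenotypeMatrix(
            [f"i{k}" for k in range(10)], ["L1"], calls,
            np.array(["P"] * 10, dtype=object),
        )
        assert np.isnan(hwe_test(g, "L1", "P").p_value)

    def test_mc_p_close_to_exact_enumeration(self):
        # n=4 diploids, 2 alleles with 4 copies each; enumerate all ways to
        # pair the 8 gene copies into genotypes conditional on allele counts
        calls = np.array([[[1, 1]], [[1, 1]], [[2, 2]], [[2, 2]]], dtype=np.int64)
        g = GenotypeMatrix(list("abcd"), ["L1"], calls, np.array(["P"] * 4, dtype=object))
        pool = [1, 1, 1, 1, 2, 2, 2, 2]
        from ssrtrace.diversity import _genotype_counts, _hwe_chisq

        alleles, counts = _genotype_counts(g.calls[:, 0, :])
        obs = _hwe_chisq(counts, alleles, 4)
        geq = tot = 0
        for perm in itertools.permutations(pool):
            geno = sorted(tuple(sorted(perm[2 * i : 2 * i + 2])) for i in range(4))
            c = {}
            for gg in geno:
                c[gg] = c.get(gg, 0) + 1
            stat = _hwe_chisq(c, alleles, 4)
            tot += 1
            geq += stat >= obs - 1e-12
        exact = geq / tot
        res = hwe_test(g, "L1", "P", n_mc=3000, seed=2)
        assert res.p_value == pytest.approx(exact, abs=0.03)


class TestLdTest:
    def test_duplicated_locus_minimal_p(self):
        rng = np.random.default_rng(4)
        locus = rng.integers(1, 4, size=(40, 1, 2))
        calls = np.concatenate([locus, locus], axis=1)
        g = GenotypeMatrix(
            [f"i{k}" for k in range(40)], ["L1", "L2"], calls,
            np.array(["P"] * 40, dtype=object),
        )
        res = ld_test(g, ("L1", "L2"), "P", n_perm=200, seed=1)
        assert res.p_value == pytest.approx(1 / 201, abs=1e-9)

    def test_allele_relabeling_invariance(self):
        rng = np.random.default_rng(8)
        calls = rng.integers(1, 4, size=(30, 2, 2))
        g1 = GenotypeMatrix(
            [f"i{k}" for k in range(30)], ["L1", "L2"], calls,
            np.array(["P"] * 30, dtype=object),
        )
        relabeled = calls.copy()
        relabeled[:, 0, :] = 10 - calls[:, 0, :]  # bijective relabeling
        g2 = GenotypeMatrix(
            [f"i{k}" for k in range(30)], ["L1", "L2"], relabeled,
            np.array(["P"] * 30, dtype=object),
        )
        r1 = ld_test(g1, ("L1", "L2"), "P", n_perm=300, seed=3)
        r2 = ld_test(g2, ("L1", "L2"), "P", n_perm=300, seed=3)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_independent_loci_uniform_p(self):
        rng = np.random.default_rng(21)
        pvals = []
        for rep in range(60):
            calls = rng.integers(1, 4, size=(40, 2, 2))
            g = GenotypeMatrix(
                [f"i{k}" for k in range(40)], ["L1", "L2"], calls,
                np.array(["P"] * 40, dtype=object),
            )
            pvals.append(ld_test(g, ("L1", "L2"), "P", n_perm=99, seed=rep).p_value)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestByCorrection:
    def test_single_p_unchanged(self):
        assert by_correction([0.04]) == pytest.approx([0.04])

    def test_hand_computed_step_up(self):
        # m=3, c(3)=1.8333: raw (0.01,0.02,0.03) -> all 0.055
        out = by_correction([0.01, 0.02, 0.03])
        assert out == pytest.approx([0.055, 0.055, 0.055], abs=1e-12)

    def test_dominates_benjamini_hochberg(self):
        rng = np.random.default_rng(2)
        p = rng.random(40)
        from statsmodels.stats.multitest import multipletests

        bh = multipletests(p, method="fdr_bh")[1]
        by = by_correction(p)
        assert (by >= bh - 1e-12).all()

    def test_matches_statsmodels_by(self):
        rng = np.random.default_rng(6)
        p = rng.random(25)
        from statsmodels.stats.multitest import multipletests

        ref = multipletests(p, method="fdr_by")[1]
        assert by_correction(p) == pytest.approx(ref, abs=1e-12)

    def test_empty_vector(self):
        assert by_correction([]).size == 0


class TestHePermutationTest:
    def test_identical_groups_p_one(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(1, 5, size=(20, 3, 2))
        dup = np.concatenate([calls, calls])
        pops = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
        g = GenotypeMatrix([f"i{k}" for k in range(40)], ["L1", "L2", "L3"], dup, pops)
        res = he_permutation_test(g, "A", "B", n_perm=99, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_divergent_diversity_detected(self):
        rng = np.random.default_rng(10)
        low = rng.choice([1, 2], p=[0.95, 0.05], size=(50, 5, 2))
        high = rng.integers(1, 10, size=(50, 5, 2))
        calls = np.concatenate([low, high])
        pops = np.array(["A"] * 50 + ["B"] * 50, dtype=object)
        g = GenotypeMatrix(
            [f"i{k}" for k in range(100)], [f"L{j}" for j in range(5)], calls, pops
        )
        res = he_permutation_test(g, "A", "B", n_perm=199, seed=0)
        assert res.p_value <= 0.01
        # observed statistic is the plain He difference
        assert res.statistic == pytest.approx(
            mean_expected_het(g, "A") - mean_expected_het(g, "B")
        )


class TestPairedHeComparison:
    def test_identical_vectors_flagged(self):
        res = paired_he_comparison([0.3] * 11, [0.3] * 11, method="wilcoxon")
        assert np.isnan(res.p_value) and res.note

    def test_systematic_shift_detected(self):
        a = np.linspace(0.3, 0.7, 11)
        res = paired_he_comparison(a, a + 0.2, method="wilcoxon")
        assert res.p_value < 0.01

    def test_mood_equal_medians(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0.5, 0.05, 30)
        b = rng.normal(0.5, 0.05, 25)
        res = paired_he_comparison(a, b, method="mood")
        assert res.p_value > 0.05


class TestEvannoDeltaK:
    def test_linear_likelihood_zero_delta(self):
        tab = pd.DataFrame({"K": [1, 2, 3, 4], "mean": [-100, -90, -80, -70], "sd": [1, 1, 1, 1]})
        out = evanno_delta_k(tab)
        inner = out["delta_k"].iloc[1:-1]
        assert (inner == 0).all()
        assert np.isnan(out["delta_k"].iloc[0]) and np.isnan(out["delta_k"].iloc[-1])

    def test_sharp_elbow_detected(self):
        tab = pd.DataFrame(
            {"K": [1, 2, 3, 4, 5], "mean": [-200, -100, -95, -92, -90], "sd": [2] * 5}
        )
        out = evanno_delta_k(tab)
        assert out.attrs["best_k"] == 2

    def test_scale_invariance(self):
        tab = pd.DataFrame(
            {"K": [1, 2, 3, 4], "mean": [-200.0, -100, -95, -92], "sd": [2.0] * 4}
        )
        scaled = tab.assign(mean=tab["mean"] * 3, sd=tab["sd"] * 3)
        a = evanno_delta_k(tab)["delta_k"]
        b = evanno_delta_k(scaled)["delta_k"]
        assert a.iloc[1] == pytest.approx(b.iloc[1])

    def test_zero_sd_flagged(self):
        tab = pd.DataFrame({"K": [1, 2, 3], "mean": [-3.0, -2, -1.5], "sd": [1.0, 0.0, 1.0]})
        out = evanno_delta_k(tab)
        assert np.isnan(out["delta_k"].iloc[1])
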