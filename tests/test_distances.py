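"""Distances, NJ trees, PCoA, AMOVA, Mantel, geographic distances."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.spatial import procrustes

from ssrtrace.genotype_io import GenotypeMatrix
from ssrtrace.distances import (
    DistanceMatrix,
    amova,
    _amova_components,
    bootstrap_support,
    geographic_distance_matrix,
    haversine_km,
    individual_distance_matrix,
    mantel_spearman,
    nei_distance,
    nei_distance_matrix,
    nj_tree,
    pairwise_fst_matrix,
    pcoa,
)


class TestNeiDistance:
    def test_identical_zero(self):
        f = {"L1": {1: 0.5, 2: 0.5}}
        assert nei_distance(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluation(self):
        d = nei_distance({"L1": {1: 1.0}}, {"L1": {1: 0.5, 2: 0.5}})
        assert d == pytest.approx(-np.log(0.5 / np.sqrt(0.5)), abs=1e-12)

    def test_non_negative_random(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pa = rng.dirichlet(np.ones(4))
            pb = rng.dirichlet(np.ones(4))
            a = {"L1": dict(zip(range(4), pa))}
            b = {"L1": dict(zip(range(4), pb))}
            assert nei_distance(a, b) >= -1e-12

    def test_disjoint_supports_infinite(self):
        assert nei_distance({"L1": {1: 1.0}}, {"L1": {2: 1.0}}) == np.inf


def test_pairwise_fst_panmictic_near_zero():
    rng = np.random.default_rng(33)
    calls = rng.integers(1, 8, size=(120, 6, 2))
    pops = np.array(["A"] * 40 + ["B"] * 40 + ["C"] * 40, dtype=object)
    g = GenotypeMatrix(
        [f"i{k}" for k in range(120)], [f"L{j}" for j in range(6)], calls, pops
    )
    m = pairwise_fst_matrix(g)
    assert np.allclose(m.values, m.values.T)
    assert np.allclose(np.diag(m.values), 0)
    assert np.abs(m.condensed()).max() < 0.02 + 0.02


class TestNjTree:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = nj_tree(DistanceMatrix(list("ABC"), d))
        # 3-point solution: a=2, b=3, c=7
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] + lengths["B"] == pytest.approx(5)
        assert lengths["A"] + lengths["C"] == pytest.approx(9)
        assert lengths["B"] + lengths["C"] == pytest.approx(10)

    def test_additive_four_taxon_recovery(self):
        # tree ((A,B),(C,D)) with internal edge 3
        d = np.array(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float
        )
        tree = nj_tree(DistanceMatrix(list("ABCD"), d))
        for a, b in [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")]:
            i, j = "ABCD".index(a), "ABCD".index(b)
            assert tree.find(a).distance(tree.find(b)) == pytest.approx(d[i, j])

    def test_newick_round_trip(self):
        import io
        from skbio.tree import TreeNode

        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        tree = nj_tree(DistanceMatrix(list("XYZ"), d))
        back = TreeNode.read(io.StringIO(str(tree)))
        assert {t.name for t in back.tips()} == {"X", "Y", "Z"}

    def test_nan_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(list("ABC"), d))


class TestBootstrapSupport:
    def test_duplicated_loci_full_support_and_determinism(self):
        rng = np.random.default_rng(10)
        base = rng.integers(1, 6, size=(48, 1, 2))
        # strong structure: shift allele ranges by population
        pops = np.array(["A"] * 12 + ["B"] * 12 + ["C"] * 12 + ["D"] * 12, dtype=object)
        base[12:24] += 10
        base[24:36] += 20
        base[36:] += 24
        calls = np.tile(base, (1, 10, 1))
        g = GenotypeMatrix(
            [f"i{k}" for k in range(48)], [f"L{j}" for j in range(10)], calls, pops
        )
        t1 = bootstrap_support(g, n_boot=50, seed=4)
        supports = [
            float(n.name) for n in t1.non_tips(include_self=False) if n.name is not None
        ]
        assert supports and all(s == 100.0 for s in supports)
        t2 = bootstrap_support(g, n_boot=50, seed=4)
        assert str(t1) == str(t2)

    def test_chord_metric_bootstrap_runs(self):
        rng = np.random.default_rng(6)
        calls = rng.integers(1, 5, size=(30, 4, 2))
        calls[15:] += 8
        pops = np.array(["A"] * 10 + ["B"] * 5 + ["C"] * 10 + ["D"] * 5, dtype=object)
        g = GenotypeMatrix(
            [f"i{k}" for k in range(30)], [f"L{j}" for j in range(4)], calls, pops
        )
        tree = bootstrap_support(g, metric="dch", n_boot=5, seed=1)
        assert {t.name for t in tree.tips()} == {"A", "B", "C", "D"}

    def test_single_locus_refused(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(1, 4, size=(10, 1, 2))
        g = GenotypeMatrix(
            [f"i{k}" for k in range(10)], ["L1"], calls,
            np.array(["A"] * 5 + ["B"] * 5, dtype=object),
        )
        with pytest.raises(ValueError):
            bootstrap_support(g, n_boot=10, seed=0)


class TestPcoa:
    def test_planar_configuration_recovered(self):
        pts = np.array([[0, 0], [1, 0], [0, 2], [3, 1], [2, 2]], float)
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix(list("abcde"), D))
        _, _, disparity = procrustes(pts, res.coordinates[:, :2])
        assert disparity < 1e-8
        assert res.explained.sum() <= 1 + 1e-9

    def test_duplicate_individuals_identical_coordinates(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(1, 5, size=(6, 3, 2))
        calls[3] = calls[0]  # clone
        g = GenotypeMatrix(
            [f"i{k}" for k in range(6)], ["L1", "L2", "L3"], calls,
            np.array(["P"] * 6, dtype=object),
        )
        dm = individual_distance_matrix(g)
        res = pcoa(dm)
        assert np.allclose(res.coordinates[0], res.coordinates[3], atol=1e-8)


class TestAmova:
    def test_brute_force_components(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(1, 5, size=(12, 2, 2))
        pops = np.array(["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4, dtype=object)
        g = GenotypeMatrix([f"i{k}" for k in range(12)], ["L1", "L2"], calls, pops)
        comps, _ = _amova_components(g, pops)

        # independent nested-ANOVA oracle (equal sizes)
        SSa = SSb = SSw = 0.0
        for j in range(2):
            alleles = np.unique(calls[:, j, :])
            X = np.zeros((24, len(alleles)))
            cp, ci = [], []
            r = 0
            for i in range(12):
                for k in (0, 1):
                    X[r] = alleles == calls[i, j, k]
                    cp.append(pops[i])
                    ci.append(i)
                    r += 1
            cp, ci = np.array(cp, dtype=object), np.array(ci)
            grand = X.mean(0)
            for p in np.unique(pops):
                sel = cp == p
                pm = X[sel].mean(0)
                SSa += sel.sum() * ((pm - grand) ** 2).sum()
                for i in np.unique(ci[sel]):
                    isel = ci == i
                    im = X[isel].mean(0)
                    SSb += isel.sum() * ((im - pm) ** 2).sum()
                    SSw += ((X[isel] - im) ** 2).sum()
        P, m, c, L = 3, 4, 2, 2
        MSa, MSb, MSw = SSa / ((P - 1) * L), SSb / ((P * m - P) * L), SSw / (P * m * L)
        sw = MSw
        sb = (MSb - sw) / c
        sa = (MSa - sw - c * sb) / (m * c)
        assert comps["among_pop"] == pytest.approx(sa, abs=1e-10)
        assert comps["among_ind"] == pytest.approx(sb, abs=1e-10)
        assert comps["within_ind"] == pytest.approx(sw, abs=1e-10)

    def test_cloned_pool_no_structure(self):
        rng = np.random.default_rng(8)
        calls = rng.integers(1, 6, size=(45, 3, 2))
        pops = np.array(["A"] * 15 + ["B"] * 15 + ["C"] * 15, dtype=object)
        g = GenotypeMatrix([f"i{k}" for k in range(45)], ["L1", "L2", "L3"], calls, pops)
        res = amova(g, n_perm=49, seed=0)
        assert abs(res.percentages["among_pop"]) < 10
        assert res.p_values["among_pop"] > 0.05
        assert sum(res.percentages.values()) == pytest.approx(100, abs=0.01)

    def test_fixed_differences_all_between(self):
        calls = np.concatenate(
            [np.full((10, 2, 2), 3, dtype=np.int64), np.full((10, 2, 2), 7, dtype=np.int64)]
        )
        pops = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
        g = GenotypeMatrix([f"i{k}" for k in range(20)], ["L1", "L2"], calls, pops)
        res = amova(g, n_perm=19, seed=0)
        assert res.percentages["among_pop"] == pytest.approx(100, abs=1e-6)


class TestMantel:
    def test_monotone_transform_rho_one(self):
        rng = np.random.default_rng(3)
        pts = rng.random((6, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        d1 = DistanceMatrix(list("abcdef"), D)
        d2 = DistanceMatrix(list("abcdef"), D**2)
        res = mantel_spearman(d1, d2, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_null_uniform_p(self):
        rng = np.random.default_rng(7)
        pvals = []
        for rep in range(40):
            a = rng.random((6, 6))
            b = rng.random((6, 6))
            a = (a + a.T) / 2
            b = (b + b.T) / 2
            np.fill_diagonal(a, 0)
            np.fill_diagonal(b, 0)
            res = mantel_spearman(
                DistanceMatrix(list("abcdef"), a),
                DistanceMatrix(list("abcdef"), b),
                n_perm=199,
                seed=rep,
            )
            pvals.append(res.p_value)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_small_matrix_refused(self):
        d = DistanceMatrix(list("abc"), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            mantel_spearman(d, d)

    def test_agrees_with_skbio(self):
        from skbio.stats.distance import mantel as skbio_mantel, DistanceMatrix as SkDM

        rng = np.random.default_rng(9)
        pts = rng.random((7, 2))
        D1 = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        D2 = D1 + rng.normal(0, 0.05, D1.shape)
        D2 = (D2 + D2.T) / 2
        np.fill_diagonal(D2, 0)
        D2 = np.abs(D2)
        res = mantel_spearman(
            DistanceMatrix(list("abcdefg"), D1),
            DistanceMatrix(list("abcdefg"), D2),
            n_perm=999,
            seed=0,
        )
        rho_ref, p_ref, _ = skbio_mantel(
            SkDM(D1), SkDM(D2), method="spearman", permutations=999, alternative="greater"
        )
        assert res.statistic == pytest.approx(rho_ref, abs=1e-9)
        assert res.p_value == pytest.approx(p_ref, abs=0.05)


def test_phylip_lower_triangle_export(tmp_path):
    d = DistanceMatrix(["AA", "BB", "CC"], np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], float))
    path = tmp_path / "d.phy"
    d.to_phylip(path)
    lines = path.read_text().splitlines()
    assert lines[0] == "3"
    assert lines[1].startswith("AA")
    assert lines[3].split()[1:] == ["2.000000", "3.000000"]


class TestGeographicDistance:
    def test_identical_points_zero(self):
        assert haversine_km(1.0, 2.0, 1.0, 2.0) == 0.0

    def test_one_degree_latitude(self):
        assert haversine_km(0, 0, 1, 0) == pytest.approx(111.19, abs=0.1)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(-5, 5, size=(6, 2))
        for i in range(6):
            for j in range(6):
                dij = haversine_km(*pts[i], *pts[j])
                assert dij == pytest.approx(haversine_km(*pts[j], *pts[i]))
                for k in range(6):
                    assert dij <= (
                        haversine_km(*pts[i], *pts[k]) + haversine_km(*pts[k], *pts[j]) + 1e-9
                    )

    def test_group_centroids(self):
        calls = np.full((4, 1, 2), 5, dtype=np.int64)
        coords = np.array([[0, 0], [0, 2], [1, 0], [1, 2]], float)
        g = GenotypeMatrix(
            list("abcd"), ["L1"], calls,
            np.array(["A", "A", "B", "B"], dtype=object), coords=coords,
        )
        dm = geographic_distance_matrix(g)
        assert dm.values[0, 1] == pytest.approx(haversine_km(0, 1, 1, 1), rel=1e-6)
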