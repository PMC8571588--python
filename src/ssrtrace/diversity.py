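"""Per-population diversity statistics, rarefaction, and resampling tests.

Covers Nei's unbiased gene diversity, observed heterozygosity, F_IS,
rarefied allelic richness and private alleles, Hardy-Weinberg and linkage
tests with Monte-Carlo nulls, the Benjamini-Yekutieli FDR correction, a
permutation test for He differences between populations, and the Evanno
second-difference (delta-K) statistic for choosing a cluster number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from ssrtrace.genotype_io import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeMatrix,
    allele_frequencies,
)

DEFAULT_SEED = 20210417


@dataclass
class TestResult:
    """Outcome of a statistical test, with optional FDR-adjusted p."""

    statistic: float
    p_value: float
    method: str
    adjusted_p: float | None = None
    n_permutations: int | None = None
    note: str | None = None


# ---------------------------------------------------------------------------
# Heterozygosity and F_IS
# ---------------------------------------------------------------------------


def expected_het(freqs, gene_count: int) -> float:
    """Nei's unbiased gene diversity (n/(n-1)) * (1 - sum p_i^2).

    ``gene_count`` is the number of gene copies the frequencies were
    estimated from (2 x non-missing diploid individuals).
    """
    p = np.asarray(list(freqs.values()) if isinstance(freqs, dict) else freqs, dtype=float)
    if gene_count < 2:
        raise ValueError("gene_count must be >= 2 for the unbiased estimator")
    if p.size and abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("frequencies must sum to 1")
    n = gene_count
    return (n / (n - 1)) * (1.0 - float(np.square(p).sum()))


def observed_het(g: GenotypeMatrix, locus, population) -> float:
    """Fraction of non-missing individuals heterozygous at a locus."""
    j = g.loci.index(locus)
    rows = g.population == population
    cell = g.calls[rows, j, :]
    ok = cell[:, 0] != MISSING
    if not ok.any():
        raise ValueError(f"all calls missing at {locus!r} in {population!r}")
    het = cell[ok, 0] != cell[ok, 1]
    return float(het.mean())


def fis(ho: float, he: float) -> float:
    """Inbreeding coefficient 1 - Ho/He; NaN when He = 0 (monomorphic)."""
    if he < 0:
        raise ValueError("He must be non-negative")
    if he == 0:
        return float("nan")
    return 1.0 - ho / he


def mean_expected_het(g: GenotypeMatrix, population, freq_table: AlleleFrequencyTable | None = None) -> float:
    """Unbiased He averaged over loci with data in one population."""
    table = freq_table or allele_frequencies(g)
    vals = []
    for locus in g.loci:
        key = (locus, population)
        if key in table.freqs and table.gene_counts[key] >= 2:
            vals.append(expected_het(table.freqs[key], table.gene_counts[key]))
    if not vals:
        raise ValueError(f"no typed loci in population {population!r}")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------


def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_allelic_richness(counts, g: int) -> float:
    """Expected number of distinct alleles in a subsample of ``g`` genes.

    ``counts`` are per-allele gene-copy counts at one locus in one
    population (total N).  The hypergeometric form sums, over alleles,
    1 - C(N - N_i, g)/C(N, g): the probability the allele appears in the
    subsample.  ``g = N`` returns the observed allele count exactly.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    N = int(counts.sum())
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds gene count N={N}")
    if g < 1:
        raise ValueError("g must be >= 1")
    total = 0.0
    for ni in counts:
        if N - ni < g:
            total += 1.0
        else:
            total += 1.0 - math.exp(_log_comb(N - ni, g) - _log_comb(N, g))
    return total


def rarefied_private_allelic_richness(
    freq_table: AlleleFrequencyTable, focal, g: int, universe=None
) -> float:
    """Expected number of alleles private to ``focal`` in g-gene subsamples.

    Kalinowski-style: for each allele at each locus, the probability it is
    seen in a g-gene subsample of the focal population times the
    probability it is missed in g-gene subsamples of every other
    population of the universe.  Loci where any population has fewer than
    g genes are skipped.
    """
    universe = list(freq_table.groups) if universe is None else list(universe)
    others = [p for p in universe if p != focal]
    total = 0.0
    for locus in freq_table.loci:
        key = (locus, focal)
        if key not in freq_table.freqs or freq_table.gene_counts[key] < g:
            continue
        if any(
            (locus, o) not in freq_table.gene_counts or freq_table.gene_counts[(locus, o)] < g
            for o in others
        ):
            continue
        N_f = freq_table.gene_counts[key]
        for allele, p in freq_table.freqs[key].items():
            ni = round(p * N_f)
            if N_f - ni < g:
                pr_in_focal = 1.0
            else:
                pr_in_focal = 1.0 - math.exp(_log_comb(N_f - ni, g) - _log_comb(N_f, g))
            pr_absent_elsewhere = 1.0
            for o in others:
                N_o = freq_table.gene_counts[(locus, o)]
                no = round(freq_table.freqs[(locus, o)].get(allele, 0.0) * N_o)
                if N_o - no < g:
                    pr_absent_elsewhere = 0.0
                    break
                pr_absent_elsewhere *= math.exp(_log_comb(N_o - no, g) - _log_comb(N_o, g))
            total += pr_in_focal * pr_absent_elsewhere
    return total


def private_alleles(freq_table: AlleleFrequencyTable, focal_partition=None) -> dict:
    """Count alleles observed in exactly one population of the partition.

    ``focal_partition`` restricts the universe of populations compared
    (e.g. islands only); defaults to all populations in the table.
    """
    universe = list(freq_table.groups) if focal_partition is None else list(focal_partition)
    if len(universe) < 2:
        import warnings

        warnings.warn("single-population partition: every allele is private")
    counts = {p: 0 for p in universe}
    for locus in freq_table.loci:
        presence: dict[int, list] = {}
        for p in universe:
            for allele in freq_table.freqs.get((locus, p), {}):
                presence.setdefault(allele, []).append(p)
        for allele, pops in presence.items():
            if len(pops) == 1:
                counts[pops[0]] += 1
    return counts


# ---------------------------------------------------------------------------
# HWE / LD tests
# ---------------------------------------------------------------------------


def _genotype_counts(cell: np.ndarray) -> tuple[np.ndarray, dict]:
    """Observed genotype counts {(a<=b): n} and the allele support."""
    ok = cell[:, 0] != MISSING
    geno = np.sort(cell[ok], axis=1)
    counts: dict = {}
    for a, b in geno:
        counts[(int(a), int(b))] = counts.get((int(a), int(b)), 0) + 1
    alleles = np.unique(geno)
    return alleles, counts


def _hwe_chisq(counts: dict, alleles: np.ndarray, n: int) -> float:
    freqs = {int(a): 0.0 for a in alleles}
    for (a, b), c in counts.items():
        freqs[a] += c
        freqs[b] += c
    total = 2 * n
    for a in freqs:
        freqs[a] /= total
    stat = 0.0
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            a, b = int(a), int(b)
            exp = n * (freqs[a] ** 2 if a == b else 2 * freqs[a] * freqs[b])
            obs = counts.get((min(a, b), max(a, b)), 0)
            if exp > 0:
                stat += (obs - exp) ** 2 / exp
    return stat


def hwe_test(
    g: GenotypeMatrix, locus, population, n_mc: int = 1000, seed: int = DEFAULT_SEED
) -> TestResult:
    """Chi-square HWE goodness-of-fit with a Monte-Carlo p-value.

    The null distribution is built by shuffling the observed gene copies
    into random diploid genotypes (permutation conditional on the allele
    counts), which sidesteps the chi-square's small-expected-count
    fragility with many microsatellite alleles.
    """
    j = g.loci.index(locus)
    rows = g.population == population
    cell = g.calls[rows, j, :]
    alleles, counts = _genotype_counts(cell)
    n = sum(counts.values())
    if len(alleles) < 2:
        return TestResult(float("nan"), float("nan"), "hwe-mc", note="monomorphic: NA")
    note = "low power: fewer than 5 individuals" if n < 5 else None
    obs_stat = _hwe_chisq(counts, alleles, n)
    pool = np.sort(cell[cell[:, 0] != MISSING], axis=1).ravel()
    rng = np.random.default_rng(seed)
    geq = 0
    for _ in range(n_mc):
        perm = rng.permutation(pool).reshape(-1, 2)
        perm.sort(axis=1)
        c: dict = {}
        for a, b in perm:
            c[(int(a), int(b))] = c.get((int(a), int(b)), 0) + 1
        if _hwe_chisq(c, alleles, n) >= obs_stat - 1e-12:
            geq += 1
    p = (geq + 1) / (n_mc + 1)
    return TestResult(obs_stat, p, "hwe-mc", n_permutations=n_mc, note=note)


def ld_test(
    g: GenotypeMatrix,
    locus_pair: tuple,
    population,
    n_perm: int = 1000,
    seed: int = DEFAULT_SEED,
) -> TestResult:
    """Permutation test of genotypic association between two loci.

    The statistic is the contingency chi-square of the two-locus genotype
    table; the null permutes individuals' single-locus genotypes at the
    second locus, breaking any between-locus association while keeping
    both single-locus genotype distributions fixed.
    """
    j1 = g.loci.index(locus_pair[0])
    j2 = g.loci.index(locus_pair[1])
    rows = g.population == population
    c1 = g.calls[rows, j1, :]
    c2 = g.calls[rows, j2, :]
    ok = (c1[:, 0] != MISSING) & (c2[:, 0] != MISSING)
    g1 = ["/".join(map(str, sorted(x))) for x in c1[ok]]
    g2 = ["/".join(map(str, sorted(x))) for x in c2[ok]]
    if len(set(g1)) < 2 or len(set(g2)) < 2:
        return TestResult(float("nan"), float("nan"), "ld-perm", note="monomorphic: NA")

    def chisq(a_list, b_list) -> float:
        tab = pd.crosstab(pd.Series(a_list), pd.Series(b_list)).to_numpy()
        exp = tab.sum(1, keepdims=True) * tab.sum(0, keepdims=True) / tab.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = np.where(exp > 0, (tab - exp) ** 2 / exp, 0.0)
        return float(contrib.sum())

    obs = chisq(g1, g2)
    rng = np.random.default_rng(seed)
    g2_arr = np.array(g2, dtype=object)
    geq = 0
    for _ in range(n_perm):
        if chisq(g1, list(rng.permutation(g2_arr))) >= obs - 1e-12:
            geq += 1
    p = (geq + 1) / (n_perm + 1)
    return TestResult(obs, p, "ld-perm", n_permutations=n_perm)


# ---------------------------------------------------------------------------
# Multiple testing and He comparisons
# ---------------------------------------------------------------------------


def by_correction(pvals) -> np.ndarray:
    """Benjamini-Yekutieli step-up FDR adjustment.

    Like Benjamini-Hochberg but inflated by the harmonic factor
    c(m) = sum_{i<=m} 1/i, valid under arbitrary dependence.  Monotone in
    rank and capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * c_m * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def he_permutation_test(
    g: GenotypeMatrix, pop_a, pop_b, n_perm: int = 999, seed: int = DEFAULT_SEED
) -> TestResult:
    """Two-sided permutation test for a difference in mean He.

    Individuals are permuted between the two populations and the mean
    unbiased He difference recomputed each time.
    """
    idx = np.flatnonzero((g.population == pop_a) | (g.population == pop_b))
    sub = g.subset(idx)
    n_a = int((sub.population == pop_a).sum())

    def delta(labels: np.ndarray) -> float:
        tmp = GenotypeMatrix(sub.individuals, sub.loci, sub.calls, labels)
        return mean_expected_het(tmp, "A") - mean_expected_het(tmp, "B")

    base = np.array(["A"] * n_a + ["B"] * (sub.n_individuals - n_a), dtype=object)
    ordered = np.where(sub.population == pop_a, "A", "B").astype(object)
    obs = delta(ordered)
    rng = np.random.default_rng(seed)
    geq = 0
    for _ in range(n_perm):
        if abs(delta(rng.permutation(base))) >= abs(obs) - 1e-12:
            geq += 1
    p = (geq + 1) / (n_perm + 1)
    return TestResult(obs, p, "he-perm", n_permutations=n_perm)


def paired_he_comparison(he_a, he_b, method: str = "wilcoxon") -> TestResult:
    """Compare per-locus He vectors with Wilcoxon signed-rank or Mood's median."""
    a = np.asarray(he_a, dtype=float)
    b = np.asarray(he_b, dtype=float)
    if method == "wilcoxon":
        if a.shape != b.shape:
            raise ValueError("wilcoxon requires equal-length paired vectors")
        if np.allclose(a, b):
            return TestResult(0.0, float("nan"), "wilcoxon", note="all differences zero")
        stat, p = sps.wilcoxon(a, b)
        return TestResult(float(stat), float(p), "wilcoxon")
    if method == "mood":
        stat, p, _, _ = sps.median_test(a, b)
        return TestResult(float(stat), float(p), "mood")
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------


def evanno_delta_k(loglik: pd.DataFrame) -> pd.DataFrame:
    """Evanno second-difference statistic over clustering log-likelihoods.

    ``loglik`` has columns ``K``, ``mean`` and ``sd`` (over replicate
    runs).  delta-K(K) = |L(K+1) - 2 L(K) + L(K-1)| / sd(K); the endpoints
    are undefined.  The result carries a ``best_k`` attribute (argmax over
    defined values).
    """
    df = loglik.sort_values("K").reset_index(drop=True)
    if len(df) < 3:
        raise ValueError("delta-K needs at least 3 consecutive K values")
    ks = df["K"].to_numpy()
    if not np.array_equal(np.diff(ks), np.ones(len(ks) - 1)):
        raise ValueError("K values must be consecutive integers")
    mean = df["mean"].to_numpy(dtype=float)
    sd = df["sd"].to_numpy(dtype=float)
    dk = np.full(len(df), np.nan)
    for i in range(1, len(df) - 1):
        if sd[i] > 0:
            dk[i] = abs(mean[i + 1] - 2 * mean[i] + mean[i - 1]) / sd[i]
    out = df.assign(delta_k=dk)
    defined = out.dropna(subset=["delta_k"])
    out.attrs["best_k"] = (
        int(defined.loc[defined["delta_k"].idxmax(), "K"]) if len(defined) else None
    )
    return out


# ---------------------------------------------------------------------------
# Table-1-style summary
# ---------------------------------------------------------------------------


def diversity_table(
    g: GenotypeMatrix,
    rarefaction_genes: int | None = None,
    by: str = "population",
) -> pd.DataFrame:
    """Per-population diversity summary: N, A, AR, PA, Ho, He, Fis.

    AR is the rarefied allelic richness averaged over loci (skipping
    locus x population cells with fewer genes than the standard);
    multi-locus Fis uses the ratio of mean Ho to mean He rather than the
    mean of per-locus ratios.
    """
    table = allele_frequencies(g, by=by)
    labels = g.group_labels(by)
    pa = private_alleles(table)
    rows = []
    for pop in table.groups:
        n_ind = int((labels == pop).sum())
        he_vals, ho_vals, ar_vals = [], [], []
        n_alleles = 0
        for locus in g.loci:
            key = (locus, pop)
            if key not in table.freqs:
                continue
            gc = table.gene_counts[key]
            freqs = table.freqs[key]
            n_alleles += len(freqs)
            if gc >= 2:
                he_vals.append(expected_het(freqs, gc))
                j = g.loci.index(locus)
                cell = g.calls[labels == pop, j, :]
                ok = cell[:, 0] != MISSING
                ho_vals.append(float((cell[ok, 0] != cell[ok, 1]).mean()))
            if rarefaction_genes is not None and gc >= rarefaction_genes:
                counts = np.round(np.array(list(freqs.values())) * gc).astype(int)
                ar_vals.append(rarefied_allelic_richness(counts, rarefaction_genes))
        ho = float(np.mean(ho_vals))
        he = float(np.mean(he_vals))
        rows.append(
            {
                "population": pop,
                "N": n_ind,
                "A": n_alleles,
                "AR": float(np.mean(ar_vals)) if ar_vals else float("nan"),
                "PA": pa[pop],
                "Ho": ho,
                "He": he,
                "Fis": fis(ho, he),
            }
        )
    return pd.DataFrame(rows).set_index("population")
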