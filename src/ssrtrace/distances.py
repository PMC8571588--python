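"""Between-population distances, trees, ordination, AMOVA, and Mantel.

Nei (1972) standard distance and pairwise Weir-Cockerham F_ST matrices,
neighbor-joining trees with locus-bootstrap support, principal coordinates
analysis of individual-level distances, a three-level AMOVA for diploid
data, Spearman Mantel tests, and great-circle geographic distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix as SkbioDM
from skbio.stats.ordination import pcoa as skbio_pcoa
from skbio.tree import TreeNode, nj as skbio_nj

from ssrtrace.diversity import TestResult
from ssrtrace.genotype_io import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeMatrix,
    allele_frequencies,
)
from ssrtrace.null_alleles import NullAlleleEstimates, ena_fst, weir_cockerham_fst


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with a metric tag."""

    labels: list
    values: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (off-diagonal) entries, row-major."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_phylip(self, path) -> None:
        """Write the matrix in PHYLIP lower-triangle format."""
        lines = [str(len(self.labels))]
        for i, label in enumerate(self.labels):
            row = " ".join(f"{self.values[i, j]:.6f}" for j in range(i))
            lines.append(f"{str(label):<10s} {row}".rstrip())
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Nei distance
# ---------------------------------------------------------------------------


def nei_distance(freq_a: dict, freq_b: dict, loci=None) -> float:
    """Nei (1972) standard genetic distance -ln(Jxy / sqrt(Jx Jy)).

    The gene identities Jx, Jy, Jxy are summed over loci before the ratio
    is taken.  Input maps: locus -> {allele: frequency}.  Returns +inf
    when the populations share no alleles.
    """
    loci = sorted(set(freq_a) & set(freq_b), key=str) if loci is None else loci
    jx = jy = jxy = 0.0
    for locus in loci:
        x = freq_a[locus]
        y = freq_b[locus]
        jx += sum(v * v for v in x.values())
        jy += sum(v * v for v in y.values())
        jxy += sum(x[a] * y.get(a, 0.0) for a in x)
    if jxy == 0:
        return float("inf")
    return float(-math.log(jxy / math.sqrt(jx * jy)))


def _group_freq_maps(table: AlleleFrequencyTable) -> dict:
    """group -> {locus: {allele: freq}} from an AlleleFrequencyTable."""
    out: dict = {g: {} for g in table.groups}
    for (locus, grp), fmap in table.freqs.items():
        out[grp][locus] = fmap
    return out


def nei_distance_matrix(g: GenotypeMatrix, by: str = "population") -> DistanceMatrix:
    table = allele_frequencies(g, by=by)
    maps = _group_freq_maps(table)
    labels = table.groups
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = nei_distance(maps[labels[i]], maps[labels[j]])
    return DistanceMatrix(labels, d, metric="nei")


def chord_distance_matrix(
    g: GenotypeMatrix, by: str = "population", ina_correction: bool = True
) -> DistanceMatrix:
    """Pairwise Cavalli-Sforza & Edwards chord distances.

    With ``ina_correction`` (default) the null-allele EM runs per locus x
    group and the virtual null class joins the frequency vectors (the
    INA-corrected D_CH); otherwise raw frequencies are used.
    """
    from ssrtrace.null_alleles import (
        chord_distance,
        corrected_frequency_table,
        estimate_null_alleles,
    )

    if ina_correction:
        grouped = GenotypeMatrix(
            g.individuals, g.loci, g.calls, g.group_labels(by), coords=g.coords
        )
        table = corrected_frequency_table(grouped, estimate_null_alleles(grouped))
    else:
        table = allele_frequencies(g, by=by)
    maps = _group_freq_maps(table)
    labels = table.groups
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = chord_distance(
                maps[labels[i]], maps[labels[j]], ina_correction=ina_correction
            )
    return DistanceMatrix(labels, d, metric=f"dch{'-ina' if ina_correction else ''}")


def pairwise_fst_matrix(
    g: GenotypeMatrix,
    correction: str = "none",
    est: NullAlleleEstimates | None = None,
    by: str = "population",
) -> DistanceMatrix:
    """Pairwise Weir-Cockerham theta, optionally ENA null-corrected."""
    labels = list(dict.fromkeys(g.group_labels(by)))
    if correction not in ("none", "ena"):
        raise ValueError("correction must be 'none' or 'ena'")
    if correction == "ena" and est is None:
        raise ValueError("ENA correction needs NullAlleleEstimates")
    grouped = GenotypeMatrix(
        g.individuals, g.loci, g.calls, g.group_labels(by),
        coords=g.coords,
    )
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pair = [labels[i], labels[j]]
            if correction == "ena":
                theta = ena_fst(grouped, est, populations=pair)
            else:
                theta = weir_cockerham_fst(grouped, populations=pair)
            d[i, j] = d[j, i] = theta
    return DistanceMatrix(labels, d, metric=f"fst-{correction}")


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(d: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with non-negative branch lengths.

    Negative branch lengths produced by NJ are clamped to zero, with the
    deficit transferred to the adjacent (sibling) edge so path lengths
    between leaves are preserved where possible.
    """
    if len(d.labels) < 3:
        raise ValueError("NJ needs at least 3 taxa")
    if np.isnan(d.values).any():
        raise ValueError("distance matrix contains NaN")
    tree = skbio_nj(SkbioDM(d.values, [str(x) for x in d.labels]))
    for node in tree.postorder(include_self=False):
        if node.length is not None and node.length < 0:
            deficit = node.length
            node.length = 0.0
            siblings = [s for s in node.parent.children if s is not node]
            if siblings and siblings[0].length is not None:
                siblings[0].length = max(siblings[0].length + deficit, 0.0)
    return tree


def _bipartitions(tree: TreeNode, taxa: frozenset) -> set[frozenset]:
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            parts.add(min(side, taxa - side, key=sorted))
    return parts


def bootstrap_support(
    g: GenotypeMatrix,
    metric: str = "nei",
    n_boot: int = 1000,
    seed: int = 0,
    by: str = "population",
) -> TreeNode:
    """NJ tree with bootstrap support expressed as % of locus resamples.

    Loci (not individuals) are resampled with replacement; support for
    each internal edge of the reference tree is the percentage of
    replicate trees containing the same bipartition, written as the
    internal node name.
    """
    if g.n_loci < 2:
        raise ValueError("bootstrap over loci needs at least 2 loci")
    builder = {"nei": nei_distance_matrix, "dch": chord_distance_matrix}.get(metric)
    if builder is None:
        raise ValueError(f"unsupported bootstrap metric {metric!r}")
    ref = nj_tree(builder(g, by=by))
    taxa = frozenset(t.name for t in ref.tips())
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        pick = rng.integers(0, g.n_loci, size=g.n_loci)
        sub = GenotypeMatrix(
            g.individuals,
            [f"{g.loci[j]}#{k}" for k, j in enumerate(pick)],
            g.calls[:, pick, :],
            g.population,
            region=g.region,
        )
        rep = nj_tree(builder(sub, by=by))
        for part in _bipartitions(rep, taxa):
            counts[part] = counts.get(part, 0) + 1
    for node in ref.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            key = min(side, taxa - side, key=sorted)
            node.name = f"{100.0 * counts.get(key, 0) / n_boot:.0f}"
    return ref


# ---------------------------------------------------------------------------
# PCoA on individual-level distances
# ---------------------------------------------------------------------------


def individual_allele_vectors(g: GenotypeMatrix) -> tuple[np.ndarray, list]:
    """Encode each individual as within-individual allele frequencies.

    One column per (locus, allele) with values 0 / 0.5 / 1; missing loci
    are mean-imputed within the individual's population so Euclidean
    distances stay defined under missingness.
    """
    table = allele_frequencies(g)
    cols: list = []
    for locus in g.loci:
        for allele in table.support(locus):
            cols.append((locus, allele))
    X = np.full((g.n_individuals, len(cols)), np.nan)
    col_idx = {c: k for k, c in enumerate(cols)}
    for i in range(g.n_individuals):
        for j, locus in enumerate(g.loci):
            a1, a2 = g.calls[i, j]
            if a1 == MISSING:
                continue
            for allele in table.support(locus):
                k = col_idx[(locus, allele)]
                X[i, k] = ((a1 == allele) + (a2 == allele)) / 2.0
    for pop in np.unique(g.population.astype(str)):
        rows = g.population.astype(str) == pop
        block = X[rows]
        means = np.nanmean(block, axis=0)
        inds = np.where(np.isnan(block))
        block[inds] = np.take(means, inds[1])
        X[rows] = block
    X = np.nan_to_num(X, nan=0.0)  # columns missing in an entire population
    return X, cols


def individual_distance_matrix(g: GenotypeMatrix) -> DistanceMatrix:
    X, _ = individual_allele_vectors(g)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    return DistanceMatrix(list(g.individuals), d, metric="individual-euclidean")


@dataclass
class PcoaResult:
    coordinates: np.ndarray
    explained: np.ndarray  # proportion per axis (non-negative eigenvalues)
    eigenvalues: np.ndarray  # full spectrum, negatives preserved
    labels: list


def pcoa(d: DistanceMatrix) -> PcoaResult:
    """Classical metric scaling of -1/2 D^2, negative eigenvalues reported."""
    res = skbio_pcoa(SkbioDM(d.values, [str(x) for x in d.labels]), method="eigh")
    eig = res.eigvals.to_numpy()
    pos = eig.clip(min=0)
    explained = pos / pos.sum() if pos.sum() > 0 else pos
    return PcoaResult(
        coordinates=res.samples.to_numpy(),
        explained=explained,
        eigenvalues=eig,
        labels=list(d.labels),
    )


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass
class AmovaResult:
    """Three-level molecular variance decomposition for diploid data."""

    components: dict[str, float]
    percentages: dict[str, float]
    p_values: dict[str, float]
    df: dict[str, int]


def _amova_components(g: GenotypeMatrix, labels: np.ndarray) -> tuple[dict, dict]:
    """Variance components from allele-indicator sums of squares.

    Gene copies are encoded as indicator vectors over alleles; nested
    sums of squares (among populations / among individuals within
    populations / within individuals) follow the standard hierarchical
    ANOVA with unequal sample sizes.  Missing calls are skipped.  Loci are
    pooled by summing SS and df coefficients.
    """
    pops = list(dict.fromkeys(labels))
    SSa = SSb = SSw = 0.0
    # coefficients accumulate over loci because missingness varies by locus
    n_tot = 0.0
    sum_nsq_over_ntot = 0.0
    sum_csq_over_n_by_pop = 0.0
    sum_csq_over_ntot = 0.0
    n_ind_tot = 0
    n_pop_eff = 0
    for j in range(g.n_loci):
        ok = g.calls[:, j, 0] != MISSING
        if ok.sum() < 2:
            continue
        alleles = np.unique(g.calls[ok, j, :])
        A = len(alleles)
        # indicator per gene copy: (copies, A)
        copies = []
        copy_ind = []
        copy_pop = []
        for i in np.flatnonzero(ok):
            for k in (0, 1):
                vec = (alleles == g.calls[i, j, k]).astype(float)
                copies.append(vec)
                copy_ind.append(i)
                copy_pop.append(labels[i])
        X = np.array(copies)
        copy_ind = np.array(copy_ind)
        copy_pop = np.array(copy_pop, dtype=object)
        grand = X.mean(axis=0)
        present_pops = [p for p in pops if (copy_pop == p).any()]
        SSt_j = float(((X - grand) ** 2).sum())
        SSa_j = 0.0
        SSb_j = 0.0
        SSw_j = 0.0
        for p in present_pops:
            sel = copy_pop == p
            pm = X[sel].mean(axis=0)
            SSa_j += sel.sum() * float(((pm - grand) ** 2).sum())
            for i in np.unique(copy_ind[sel]):
                isel = copy_ind == i
                im = X[isel].mean(axis=0)
                SSb_j += isel.sum() * float(((im - pm) ** 2).sum())
                SSw_j += float(((X[isel] - im) ** 2).sum())
        SSa += SSa_j
        SSb += SSb_j
        SSw += SSw_j
        # df and coefficients for this locus
        inds = np.unique(copy_ind)
        n_c = len(copy_ind)
        n_i = len(inds)
        n_p = len(present_pops)
        n_ind_tot += n_i
        n_pop_eff += n_p
        pop_copy_counts = np.array([(copy_pop == p).sum() for p in present_pops], float)
        n_tot += n_c
        sum_nsq_over_ntot += (pop_copy_counts**2).sum() / n_c
        # copies per individual (2 for complete diploid calls)
        ind_counts = np.array([(copy_ind == i).sum() for i in inds], float)
        for p in present_pops:
            sel_inds = np.unique(copy_ind[copy_pop == p])
            cnts = np.array([(copy_ind == i).sum() for i in sel_inds], float)
            sum_csq_over_n_by_pop += (cnts**2).sum() / cnts.sum()
        sum_csq_over_ntot += (ind_counts**2).sum() / n_c
    # pooled degrees of freedom (summed over loci, since missingness varies)
    df = {"among_pop": 0, "among_ind": 0, "within_ind": 0}
    n_tot2 = 0
    for j in range(g.n_loci):
        ok = g.calls[:, j, 0] != MISSING
        if ok.sum() < 2:
            continue
        labs = labels[ok]
        n_i = int(ok.sum())
        n_p = len(set(labs))
        df["among_pop"] += n_p - 1
        df["among_ind"] += n_i - n_p
        df["within_ind"] += n_i  # one df per diploid individual
        n_tot2 += 2 * n_i
    # expected-mean-square coefficients (Excoffier-style, unequal sizes)
    n_prime_b = (n_tot - sum_csq_over_n_by_pop) / max(df["among_ind"], 1)
    n_prime_a = (sum_csq_over_n_by_pop - sum_csq_over_ntot) / max(df["among_pop"], 1)
    n_c_coef = (n_tot - sum_nsq_over_ntot) / max(df["among_pop"], 1)
    MSa = SSa / max(df["among_pop"], 1)
    MSb = SSb / max(df["among_ind"], 1)
    MSw = SSw / max(df["within_ind"], 1)
    sigma_w = MSw
    sigma_b = (MSb - sigma_w) / n_prime_b if n_prime_b > 0 else 0.0
    sigma_a = (MSa - sigma_w - n_prime_a * sigma_b) / n_c_coef if n_c_coef > 0 else 0.0
    comps = {
        "among_pop": sigma_a,
        "among_ind": sigma_b,
        "within_ind": sigma_w,
    }
    return comps, df


def amova(
    g: GenotypeMatrix,
    by: str = "population",
    n_perm: int = 99,
    seed: int = 0,
) -> AmovaResult:
    """Three-level AMOVA: populations / individuals within / within individuals.

    Significance: the among-population component is tested by permuting
    individuals among populations; the among-individual component by
    permuting gene copies among individuals within populations.
    """
    labels = g.group_labels(by)
    if len(set(labels)) < 2:
        raise ValueError("AMOVA needs at least 2 populations")
    import warnings

    sizes = pd.Series(list(labels)).value_counts()
    if (sizes == 1).any():
        warnings.warn("population with a single individual contributes no within-population df")
    comps, df = _amova_components(g, labels)
    total = sum(comps.values())
    percentages = {k: 100.0 * v / total for k, v in comps.items()}
    rng = np.random.default_rng(seed)
    exceed_a = exceed_b = 0
    for _ in range(n_perm):
        perm_labels = rng.permutation(labels)
        c_perm, _ = _amova_components(g, perm_labels)
        if c_perm["among_pop"] >= comps["among_pop"] - 1e-12:
            exceed_a += 1
        # permute alleles among individuals within populations
        calls = g.calls.copy()
        for pop in set(labels):
            rows = np.flatnonzero(labels == pop)
            for j in range(g.n_loci):
                block = calls[rows, j, :]
                okr = block[:, 0] != MISSING
                pool = block[okr].ravel()
                pool = rng.permutation(pool)
                block[okr] = pool.reshape(-1, 2)
                calls[rows, j, :] = block
        g_perm = GenotypeMatrix(g.individuals, g.loci, calls, g.population, region=g.region)
        c_perm2, _ = _amova_components(g_perm, labels)
        if c_perm2["among_ind"] >= comps["among_ind"] - 1e-12:
            exceed_b += 1
    p_values = {
        "among_pop": (exceed_a + 1) / (n_perm + 1),
        "among_ind": (exceed_b + 1) / (n_perm + 1),
        "within_ind": float("nan"),
    }
    return AmovaResult(comps, percentages, p_values, df)


# ---------------------------------------------------------------------------
# Mantel and geographic distance
# ---------------------------------------------------------------------------


def mantel_spearman(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 10000,
    seed: int = 0,
) -> TestResult:
    """Spearman Mantel test, one-sided for positive association.

    rho is computed over the off-diagonal upper-triangle pairs; the null
    permutes rows and columns of the second matrix jointly.
    """
    if list(map(str, d1.labels)) != list(map(str, d2.labels)):
        raise ValueError("matrices must share labels and order")
    n = len(d1.labels)
    if n < 4:
        raise ValueError("Mantel needs at least 4 labels")
    iu = np.triu_indices(n, k=1)
    obs = sps.spearmanr(d1.values[iu], d2.values[iu]).statistic
    rng = np.random.default_rng(seed)
    geq = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = sps.spearmanr(d1.values[iu], d2.values[perm][:, perm][iu]).statistic
        if r >= obs - 1e-12:
            geq += 1
    p = (geq + 1) / (n_perm + 1)
    return TestResult(float(obs), p, "mantel-spearman", n_permutations=n_perm)


EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance between two (lat, lon) points in km."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def geographic_distance_matrix(g: GenotypeMatrix, by: str = "population") -> DistanceMatrix:
    """Haversine distances between group centroids (mean member coords)."""
    if g.coords is None:
        raise ValueError("no coordinates present")
    labels_all = g.group_labels(by)
    import warnings

    centroids = {}
    labels = []
    for grp in dict.fromkeys(labels_all):
        rows = labels_all == grp
        pts = g.coords[rows]
        pts = pts[~np.isnan(pts).any(axis=1)]
        if len(pts) == 0:
            warnings.warn(f"group {grp!r} has no coordinates; excluded")
            continue
        centroids[grp] = pts.mean(axis=0)
        labels.append(grp)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = centroids[labels[i]], centroids[labels[j]]
            d[i, j] = d[j, i] = haversine_km(a[0], a[1], b[0], b[1])
    return DistanceMatrix(labels, d, metric="geographic-km")
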