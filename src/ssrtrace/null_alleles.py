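"""Null-allele EM estimation and the corrected statistics built on it.

A null allele fails to amplify, so heterozygote carriers type as apparent
homozygotes and null homozygotes type as blanks.  Assuming HWE within each
locus x population, an EM algorithm recovers the null frequency beta and
the corrected visible-allele frequencies; those feed the corrected
expected heterozygosity, the ENA-corrected Weir-Cockerham F_ST, and the
INA-corrected Cavalli-Sforza & Edwards chord distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ssrtrace.diversity import expected_het
from ssrtrace.genotype_io import (
    MISSING,
    NULL_ALLELE,
    AlleleFrequencyTable,
    GenotypeMatrix,
)


@dataclass
class EmFit:
    """EM estimate for one locus x population cell."""

    visible: dict[int, float]  # corrected visible-allele frequencies
    beta: float  # null-allele frequency; visible + beta sum to 1
    failure_rate: float  # technical-failure rate (blank mode only)
    n_iter: int
    converged: bool
    loglik: float
    loglik_path: list[float] = field(default_factory=list)

    def renormalized_visible(self) -> dict[int, float]:
        """Visible frequencies rescaled to sum to 1 (null removed)."""
        s = 1.0 - self.beta
        if s <= 0:
            raise ValueError("beta = 1: no visible alleles")
        return {a: p / s for a, p in self.visible.items()}

    def with_null(self) -> dict:
        """Frequency map including the virtual null allele class."""
        out: dict = dict(self.visible)
        out[NULL_ALLELE] = self.beta
        return out


@dataclass
class NullAlleleEstimates:
    """EM fits for every locus x population cell with data."""

    fits: dict[tuple, EmFit] = field(default_factory=dict)

    def beta(self, locus, population) -> float:
        return self.fits[(locus, population)].beta

    def mean_beta(self) -> float:
        return float(np.mean([f.beta for f in self.fits.values()]))

    def beta_table(self) -> pd.DataFrame:
        """Locus x population table of null frequencies (appendix shape)."""
        loci = sorted({k[0] for k in self.fits}, key=str)
        pops = sorted({k[1] for k in self.fits}, key=str)
        data = {
            p: [self.fits.get((l, p)).beta if (l, p) in self.fits else np.nan for l in loci]
            for p in pops
        }
        return pd.DataFrame(data, index=loci)


def _observed_classes(cell: np.ndarray) -> tuple[dict, dict, int]:
    """Split calls into het counts {(i,j): n}, hom counts {i: n}, blanks."""
    blanks = int((cell[:, 0] == MISSING).sum())
    obs = cell[cell[:, 0] != MISSING]
    het: dict = {}
    hom: dict = {}
    for a, b in np.sort(obs, axis=1):
        a, b = int(a), int(b)
        if a == b:
            hom[a] = hom.get(a, 0) + 1
        else:
            het[(a, b)] = het.get((a, b), 0) + 1
    return het, hom, blanks


def _loglik(het, hom, blanks, p, beta, f, blank_mode) -> float:
    ll = 0.0
    for (i, j), m in het.items():
        ll += m * math.log(max((1 - f) * 2 * p[i] * p[j], 1e-300))
    for i, m in hom.items():
        ll += m * math.log(max((1 - f) * (p[i] ** 2 + 2 * p[i] * beta), 1e-300))
    if blank_mode == "coestimate":
        if blanks:
            ll += blanks * math.log(max(f + (1 - f) * beta * beta, 1e-300))
    else:  # blanks excluded: condition every observation on being typed
        n_typed = sum(het.values()) + sum(hom.values())
        ll -= n_typed * math.log(max(1 - beta * beta, 1e-300))
    return ll


def em_null_frequency(
    cell_or_matrix,
    locus=None,
    population=None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    blanks: str = "coestimate",
    beta0: float = 0.1,
) -> EmFit:
    """EM estimate of the null-allele frequency at one locus x population.

    The latent-genotype model: an apparent homozygote A/A mixes true A/A
    and A/null; a blank mixes true null/null and (in ``blanks='coestimate'``
    mode) a locus-wide technical failure whose rate is co-estimated.  With
    ``blanks='ignore'`` blanks are dropped and the likelihood conditions on
    the genotype being typed.  Initialization: raw frequencies scaled by
    (1 - beta0) with beta = beta0.

    Accepts either a raw ``(n, 2)`` call array or a
    (:class:`GenotypeMatrix`, locus, population) triple.
    """
    if isinstance(cell_or_matrix, GenotypeMatrix):
        g = cell_or_matrix
        j = g.loci.index(locus)
        cell = g.calls[g.population == population, j, :]
    else:
        cell = np.asarray(cell_or_matrix)
    if blanks not in ("coestimate", "ignore"):
        raise ValueError("blanks must be 'coestimate' or 'ignore'")
    het, hom, n_blank = _observed_classes(cell)
    n_typed = sum(het.values()) + sum(hom.values())
    if n_typed == 0:
        raise ValueError("no non-missing genotypes")
    if blanks == "ignore":
        n_blank = 0

    alleles = sorted({a for pair in het for a in pair} | set(hom))
    raw_counts = {a: 0.0 for a in alleles}
    for (i, j2), m in het.items():
        raw_counts[i] += m
        raw_counts[j2] += m
    for i, m in hom.items():
        raw_counts[i] += 2 * m
    total_raw = sum(raw_counts.values())
    p = {a: (1 - beta0) * c / total_raw for a, c in raw_counts.items()}
    beta = beta0
    f = n_blank / (n_typed + n_blank) * 0.5 if n_blank else 0.0

    ll = _loglik(het, hom, n_blank, p, beta, f, blanks)
    path = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        copies = {a: 0.0 for a in alleles}
        null_copies = 0.0
        for (i, j2), m in het.items():
            copies[i] += m
            copies[j2] += m
        for i, m in hom.items():
            denom = p[i] ** 2 + 2 * p[i] * beta
            w_true = (p[i] ** 2 / denom) if denom > 0 else 1.0
            copies[i] += m * (1.0 + w_true)
            null_copies += m * (1.0 - w_true)
        if blanks == "coestimate" and n_blank:
            pr_blank = f + (1 - f) * beta * beta
            v = ((1 - f) * beta * beta / pr_blank) if pr_blank > 0 else 0.0
            genuine = n_blank * v
            null_copies += 2 * genuine
            f_new = (n_blank - genuine) / (n_typed + n_blank)
            total = 2 * (n_typed + genuine)
        else:
            # phantom null homozygotes for the truncated (conditional) model
            phantom = n_typed * beta * beta / max(1 - beta * beta, 1e-12)
            null_copies += 2 * phantom
            f_new = 0.0
            total = 2 * (n_typed + phantom)
        p_new = {a: c / total for a, c in copies.items()}
        beta_new = null_copies / total
        delta = max(
            abs(beta_new - beta),
            abs(f_new - f),
            max(abs(p_new[a] - p[a]) for a in alleles),
        )
        p, beta, f = p_new, beta_new, f_new
        path.append(_loglik(het, hom, n_blank, p, beta, f, blanks))
        if delta < tol:
            converged = True
            break
    return EmFit(
        visible=p,
        beta=beta,
        failure_rate=f,
        n_iter=it,
        converged=converged,
        loglik=path[-1],
        loglik_path=path,
    )


def estimate_null_alleles(
    g: GenotypeMatrix,
    by: str = "population",
    tol: float = 1e-6,
    max_iter: int = 1000,
    blanks: str = "coestimate",
) -> NullAlleleEstimates:
    """Run the EM over every locus x group cell with data."""
    labels = g.group_labels(by)
    est = NullAlleleEstimates()
    for grp in dict.fromkeys(labels):
        rows = labels == grp
        for j, locus in enumerate(g.loci):
            cell = g.calls[rows, j, :]
            if (cell[:, 0] != MISSING).sum() == 0:
                continue
            est.fits[(locus, grp)] = em_null_frequency(
                cell, tol=tol, max_iter=max_iter, blanks=blanks
            )
    return est


def corrected_frequency_table(
    g: GenotypeMatrix, est: NullAlleleEstimates, by: str = "population"
) -> AlleleFrequencyTable:
    """Frequency table of corrected visible frequencies plus the null class."""
    labels = g.group_labels(by)
    groups = list(dict.fromkeys(labels))
    table = AlleleFrequencyTable(loci=list(g.loci), groups=groups)
    for (locus, grp), fit in est.fits.items():
        table.freqs[(locus, grp)] = fit.with_null()
        rows = labels == grp
        j = g.loci.index(locus)
        cell = g.calls[rows, j, :]
        table.gene_counts[(locus, grp)] = int(2 * (cell[:, 0] != MISSING).sum())
    return table


def corrected_expected_het(est: NullAlleleEstimates, g: GenotypeMatrix, population) -> float:
    """Mean unbiased He over loci from null-corrected frequencies.

    The virtual null participates as an ordinary allele class alongside
    the corrected visible frequencies (the INA-style frequency vector);
    this is what raises He relative to the raw estimate when beta > 0 —
    renormalizing over visible alleles alone would leave He unchanged,
    because masking inflates visible allele counts proportionally.  A
    locus with beta = 1 carries no visible information and is skipped.
    """
    from ssrtrace.genotype_io import MISSING as _MISS

    vals = []
    for j, locus in enumerate(g.loci):
        key = (locus, population)
        if key not in est.fits:
            continue
        fit = est.fits[key]
        if fit.beta >= 1.0 - 1e-9:
            continue
        cell = g.calls[g.population == population, j, :]
        gc = int(2 * (cell[:, 0] != _MISS).sum())
        if gc < 2:
            continue
        vals.append(expected_het(fit.with_null(), gc))
    if not vals:
        raise ValueError(f"no usable loci for population {population!r}")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Weir-Cockerham theta, naive and ENA-corrected
# ---------------------------------------------------------------------------


def _wc_components(n, p, h):
    """Weir-Cockerham (1984) a, b, c for one allele over r populations.

    n: diploid sample sizes; p: allele frequencies; h: proportion of
    individuals heterozygous for the allele, per population.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = len(n)
    nbar = n.mean()
    if r < 2 or nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)
    if nc <= 0:
        return 0.0, 0.0, 0.0
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return float(a), float(b), float(c)


def weir_cockerham_fst(g: GenotypeMatrix, populations=None) -> float:
    """Multi-locus Weir-Cockerham theta from raw genotype data.

    Locus and allele components are combined as a ratio of sums.
    """
    pops = g.populations if populations is None else list(populations)
    if len(pops) < 2:
        raise ValueError("theta needs at least 2 populations")
    num = den = 0.0
    for j in range(g.n_loci):
        cells = []
        for pop in pops:
            cell = g.calls[g.population == pop, j, :]
            cell = cell[cell[:, 0] != MISSING]
            cells.append(cell)
        ns = np.array([len(c) for c in cells], dtype=float)
        if (ns < 2).any():
            continue
        alleles = np.unique(np.concatenate([c.ravel() for c in cells if len(c)]))
        if len(alleles) < 2:
            continue
        for allele in alleles:
            p = np.array([(c == allele).sum() / (2 * len(c)) for c in cells])
            h = np.array(
                [((c[:, 0] == allele) ^ (c[:, 1] == allele)).mean() for c in cells]
            )
            a, b, cc = _wc_components(ns, p, h)
            num += a
            den += a + b + cc
    if den == 0:
        return float("nan")
    return num / den


def ena_fst(
    g: GenotypeMatrix, est: NullAlleleEstimates, populations=None
) -> float:
    """Weir-Cockerham theta excluding null-allele contributions (ENA).

    The EM-corrected visible-allele frequencies (left on the full scale,
    summing to 1 - beta, so the null behaves as an ordinary allele class)
    replace the raw frequencies; per-allele variance components are summed
    over the visible alleles only, and the heterozygosity term is taken at
    its HWE expectation, removing the distortion apparent homozygotes
    induce.
    """
    pops = g.populations if populations is None else list(populations)
    if len(pops) < 2:
        raise ValueError("theta needs at least 2 populations")
    num = den = 0.0
    for j, locus in enumerate(g.loci):
        freqs = []
        ns = []
        for pop in pops:
            key = (locus, pop)
            if key not in est.fits:
                freqs = []
                break
            fit = est.fits[key]
            if fit.beta >= 1.0 - 1e-9:
                freqs = []
                break
            cell = g.calls[g.population == pop, j, :]
            n_typed = int((cell[:, 0] != MISSING).sum())
            if n_typed < 2:
                freqs = []
                break
            freqs.append(dict(fit.visible))
            ns.append(n_typed)
        if not freqs:
            continue
        alleles = sorted({a for fmap in freqs for a in fmap})
        if len(alleles) < 2:
            continue
        ns_arr = np.array(ns, dtype=float)
        for allele in alleles:
            p = np.array([fmap.get(allele, 0.0) for fmap in freqs])
            h = 2 * p * (1 - p)
            a, b, cc = _wc_components(ns_arr, p, h)
            num += a
            den += a + b + cc
    if den == 0:
        return float("nan")
    return num / den


# ---------------------------------------------------------------------------
# Cavalli-Sforza & Edwards chord distance
# ---------------------------------------------------------------------------


def chord_distance(
    freq_a: dict, freq_b: dict, loci=None, ina_correction: bool = False
) -> float:
    """Mean per-locus Cavalli-Sforza & Edwards chord distance.

    ``freq_a`` / ``freq_b`` map locus -> {allele: frequency}.  Per locus
    the distance is (2/pi) * sqrt(2 * (1 - sum_a sqrt(x_a y_a))) over the
    union support; with ``ina_correction`` the virtual null-allele class
    participates like any other allele (INA).  Loci missing in either
    population are excluded from the mean.
    """
    loci = sorted(set(freq_a) & set(freq_b), key=str) if loci is None else loci
    vals = []
    for locus in loci:
        if locus not in freq_a or locus not in freq_b:
            continue
        x = dict(freq_a[locus])
        y = dict(freq_b[locus])
        if not ina_correction:
            x.pop(NULL_ALLELE, None)
            y.pop(NULL_ALLELE, None)
            sx, sy = sum(x.values()), sum(y.values())
            x = {a: v / sx for a, v in x.items()}
            y = {a: v / sy for a, v in y.items()}
        support = set(x) | set(y)
        s = sum(math.sqrt(x.get(a, 0.0) * y.get(a, 0.0)) for a in support)
        vals.append((2.0 / math.pi) * math.sqrt(max(2.0 * (1.0 - s), 0.0)))
    if not vals:
        raise ValueError("no shared loci")
    return float(np.mean(vals))
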