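"""Approximate Bayesian computation for scenario choice and parameters.

The engine follows the classic rejection + regression recipe: draw
scenarios and parameters from priors, simulate SSR datasets, summarize
them with the microsatellite statistics used for invasion-route inference
(allele numbers, gene diversities, allele-size variances, pairwise F_ST,
shared-allele distance, (delta-mu)^2, admixture least-squares
proportions), retain the simulations closest to the observed vector,
estimate scenario posterior probabilities with a multinomial logistic
regression evaluated at the observed point, adjust
parameter posteriors by local-linear regression, and check the selected
model by posterior-predictive tail probabilities and a PCA projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ssrtrace.coalescent import simulate_allele_sizes
from ssrtrace.genotype_io import MISSING, GenotypeMatrix
from ssrtrace.scenarios import ScenarioSet, ScenarioTemplate

# ---------------------------------------------------------------------------
# Per-locus gene-copy representation
# ---------------------------------------------------------------------------


def pop_locus_arrays(data) -> dict[str, list[np.ndarray]]:
    """Normalize input to pop -> per-locus arrays of observed gene copies.

    Accepts a ``pop -> (n_gene_copies, n_loci)`` dict (simulator output)
    or a :class:`GenotypeMatrix` (missing calls dropped per locus).
    """
    if isinstance(data, GenotypeMatrix):
        out: dict[str, list[np.ndarray]] = {}
        for pop in data.populations:
            rows = data.population == pop
            per_locus = []
            for j in range(data.n_loci):
                cell = data.calls[rows, j, :]
                per_locus.append(cell[cell[:, 0] != MISSING].ravel())
            out[str(pop)] = per_locus
        return out
    return {
        str(pop): [arr[:, j] for j in range(arr.shape[1])]
        for pop, arr in data.items()
    }


def _genotype_pairs(data) -> dict[str, list[np.ndarray]]:
    """pop -> per-locus (n_ind, 2) sorted genotype arrays (for DAS)."""
    if isinstance(data, GenotypeMatrix):
        out: dict[str, list[np.ndarray]] = {}
        for pop in data.populations:
            rows = data.population == pop
            per_locus = []
            for j in range(data.n_loci):
                cell = data.calls[rows, j, :]
                cell = cell[cell[:, 0] != MISSING]
                per_locus.append(np.sort(cell, axis=1))
            out[str(pop)] = per_locus
        return out
    out = {}
    for pop, arr in data.items():
        per_locus = []
        for j in range(arr.shape[1]):
            per_locus.append(np.sort(arr[:, j].reshape(-1, 2), axis=1))
        out[str(pop)] = per_locus
    return out


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


@dataclass
class SummaryStatDesign:
    """Which statistics to compute, for which populations/pairs/trios.

    ``per_population`` draws from {nal, het, var}; ``per_pair`` from
    {nal, het, var, fst, das, dm2}; ``trios`` lists (admixed, parent_a,
    parent_b) admixture designs.
    """

    populations: list[str]
    pairs: list[tuple[str, str]] = field(default_factory=list)
    trios: list[tuple[str, str, str]] = field(default_factory=list)
    per_population: tuple[str, ...] = ("nal", "het", "var")
    per_pair: tuple[str, ...] = ("nal", "het", "var", "fst", "das", "dm2")

    @classmethod
    def full(cls, populations, trios=()) -> "SummaryStatDesign":
        pops = list(populations)
        pairs = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1 :]]
        return cls(pops, pairs, list(trios))

    def names(self) -> list[str]:
        out = [f"{s}_{p}" for p in self.populations for s in self.per_population]
        out += [f"{s}_{a}-{b}" for a, b in self.pairs for s in self.per_pair]
        out += [f"admix_{t[0]}|{t[1]}x{t[2]}" for t in self.trios]
        return out


def _unbiased_het(copies: np.ndarray) -> float:
    n = len(copies)
    if n < 2:
        return np.nan
    _, counts = np.unique(copies, return_counts=True)
    p = counts / n
    return (n / (n - 1)) * (1.0 - float((p**2).sum()))


class _LocusCounts:
    """Per-locus allele tallies cached for fast statistic evaluation."""

    __slots__ = ("vals", "cnts", "n", "mean", "var", "het", "nal")

    def __init__(self, copies: np.ndarray):
        self.n = len(copies)
        if self.n == 0:
            self.vals = np.empty(0, dtype=np.int64)
            self.cnts = np.empty(0, dtype=np.int64)
            self.mean = self.var = self.het = 0.0
            self.nal = 0
            return
        self.vals, self.cnts = np.unique(copies, return_counts=True)
        self.nal = len(self.vals)
        n = self.n
        s1 = float((self.cnts * self.vals).sum())
        s2 = float((self.cnts * self.vals.astype(float) ** 2).sum())
        self.mean = s1 / n
        self.var = (s2 - n * self.mean**2) / (n - 1) if n >= 2 else 0.0
        p = self.cnts / n
        self.het = (n / (n - 1)) * (1.0 - float((p**2).sum())) if n >= 2 else 0.0

    def merged(self, other: "_LocusCounts") -> "_LocusCounts":
        out = _LocusCounts(np.empty(0, dtype=np.int64))
        vals = np.concatenate([self.vals, other.vals])
        cnts = np.concatenate([self.cnts, other.cnts])
        u, inv = np.unique(vals, return_inverse=True)
        merged_cnts = np.bincount(inv, weights=cnts).astype(np.int64)
        out.vals, out.cnts = u, merged_cnts
        out.n = self.n + other.n
        out.nal = len(u)
        n = out.n
        if n >= 2:
            s1 = float((merged_cnts * u).sum())
            s2 = float((merged_cnts * u.astype(float) ** 2).sum())
            out.mean = s1 / n
            out.var = (s2 - n * out.mean**2) / (n - 1)
            p = merged_cnts / n
            out.het = (n / (n - 1)) * (1.0 - float((p**2).sum()))
        return out


def _counts_stats(loci: list[_LocusCounts], which) -> list[float]:
    nal = [c.nal for c in loci if c.n > 0]
    het = [c.het for c in loci if c.n >= 2]
    var = [c.var for c in loci if c.n >= 2]
    table = {"nal": nal, "het": het, "var": var}
    return [float(np.mean(table[s])) if table[s] else 0.0 for s in which]


def _fst_counts(ca: _LocusCounts, cb: _LocusCounts) -> tuple[float, float]:
    """Weir-Cockerham numerator/denominator over the alleles of one locus,
    two populations, heterozygosity at its HWE expectation (vectorized)."""
    if ca.n < 4 or cb.n < 4:
        return 0.0, 0.0
    union = np.unique(np.concatenate([ca.vals, cb.vals]))
    if len(union) < 2:
        return 0.0, 0.0
    p1 = np.zeros(len(union))
    p2 = np.zeros(len(union))
    p1[np.searchsorted(union, ca.vals)] = ca.cnts / ca.n
    p2[np.searchsorted(union, cb.vals)] = cb.cnts / cb.n
    n1, n2 = ca.n / 2.0, cb.n / 2.0
    r = 2
    nbar = (n1 + n2) / 2.0
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    if nc <= 0 or nbar <= 1:
        return 0.0, 0.0
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    h1 = 2 * p1 * (1 - p1)
    h2 = 2 * p2 * (1 - p2)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return float(a.sum()), float((a + b + c).sum())


def _fst_pair(pa, pb) -> float:
    counts_a = [c if isinstance(c, _LocusCounts) else _LocusCounts(c) for c in pa]
    counts_b = [c if isinstance(c, _LocusCounts) else _LocusCounts(c) for c in pb]
    num = den = 0.0
    for ca, cb in zip(counts_a, counts_b):
        a, d = _fst_counts(ca, cb)
        num += a
        den += d
    return num / den if den != 0 else 0.0


def _das_pair(ga, gb) -> float:
    """1 - mean proportion of shared alleles over loci and cross pairs."""
    shares = []
    for A, B in zip(ga, gb):
        if len(A) == 0 or len(B) == 0:
            continue
        a1 = A[:, 0][:, None]
        a2 = A[:, 1][:, None]
        b1 = B[:, 0][None, :]
        b2 = B[:, 1][None, :]
        straight = (a1 == b1).astype(np.int8) + (a2 == b2).astype(np.int8)
        crossed = (a1 == b2).astype(np.int8) + (a2 == b1).astype(np.int8)
        shared = np.maximum(straight, crossed)  # optimal 2-item matching
        shares.append(shared.mean() / 2.0)
    return 1.0 - float(np.mean(shares)) if shares else 1.0


def _dm2_pair(ca_list, cb_list) -> float:
    vals = [
        (ca.mean - cb.mean) ** 2
        for ca, cb in zip(ca_list, cb_list)
        if ca.n > 0 and cb.n > 0
    ]
    return float(np.mean(vals)) if vals else 0.0


def _admixture_alpha(c_adm, c_a, c_b) -> float:
    """Least-squares admixture coefficient over pooled allele frequencies.

    alpha minimizes ||f_adm - alpha f_a - (1 - alpha) f_b||^2 over the
    per-locus union supports, clamped to [0, 1].
    """
    num = den = 0.0
    for cm, ca, cb in zip(c_adm, c_a, c_b):
        if cm.n == 0 or ca.n == 0 or cb.n == 0:
            continue
        support = np.unique(np.concatenate([cm.vals, ca.vals, cb.vals]))
        fm = np.zeros(len(support))
        fa = np.zeros(len(support))
        fb = np.zeros(len(support))
        fm[np.searchsorted(support, cm.vals)] = cm.cnts / cm.n
        fa[np.searchsorted(support, ca.vals)] = ca.cnts / ca.n
        fb[np.searchsorted(support, cb.vals)] = cb.cnts / cb.n
        diff = fa - fb
        num += float(((fm - fb) * diff).sum())
        den += float((diff**2).sum())
    if den == 0:
        return 0.5
    return float(np.clip(num / den, 0.0, 1.0))


def summary_statistics(data, design: SummaryStatDesign) -> np.ndarray:
    """Compute the designed statistic vector; order matches ``design.names()``."""
    per_locus = pop_locus_arrays(data)
    for p in design.populations:
        if p not in per_locus or all(len(c) == 0 for c in per_locus[p]):
            raise ValueError(f"designated population {p!r} is empty")
    counts = {
        p: [_LocusCounts(c) for c in per_locus[p]] for p in design.populations
    }
    out: list[float] = []
    for p in design.populations:
        out.extend(_counts_stats(counts[p], design.per_population))
    genos = _genotype_pairs(data) if "das" in design.per_pair else None
    pooled_cache: dict = {}
    for a, b in design.pairs:
        ca_list, cb_list = counts[a], counts[b]
        pooled = pooled_cache.get((a, b))
        if pooled is None and any(s in ("nal", "het", "var") for s in design.per_pair):
            pooled = [x.merged(y) for x, y in zip(ca_list, cb_list)]
            pooled_cache[(a, b)] = pooled
        for s in design.per_pair:
            if s in ("nal", "het", "var"):
                out.append(_counts_stats(pooled, (s,))[0])
            elif s == "fst":
                out.append(_fst_pair(ca_list, cb_list))
            elif s == "das":
                out.append(_das_pair(genos[a], genos[b]))
            elif s == "dm2":
                out.append(_dm2_pair(ca_list, cb_list))
            else:
                raise ValueError(f"unknown pair statistic {s!r}")
    for adm, a, b in design.trios:
        out.append(_admixture_alpha(counts[adm], counts[a], counts[b]))
    return np.array(out, dtype=float)


# ---------------------------------------------------------------------------
# Rejection sampling
# ---------------------------------------------------------------------------


@dataclass
class ReferenceTable:
    """Simulated reference table plus the retained (accepted) subset."""

    scenario_names: list[str]
    scenario_idx: np.ndarray  # (n_sim,)
    params: pd.DataFrame  # (n_sim, n_params); NaN for params a scenario lacks
    stats: np.ndarray  # (n_sim, n_stats)
    stat_names: list[str]
    observed: np.ndarray
    retained: np.ndarray  # bool mask
    distances: np.ndarray
    stat_sd: np.ndarray

    def retained_counts(self) -> dict[str, int]:
        idx = self.scenario_idx[self.retained]
        return {
            name: int((idx == k).sum()) for k, name in enumerate(self.scenario_names)
        }

    def to_frame(self) -> pd.DataFrame:
        """Columnar view (scenario, parameters, statistics, distance,
        retained flag) suitable for CSV/Parquet persistence."""
        out = pd.DataFrame({"scenario": [self.scenario_names[k] for k in self.scenario_idx]})
        out = pd.concat([out, self.params.reset_index(drop=True)], axis=1)
        stats = pd.DataFrame(self.stats, columns=self.stat_names)
        out = pd.concat([out, stats], axis=1)
        out["distance"] = self.distances
        out["retained"] = self.retained
        return out


def simulate_reference_table(
    scenario_set: ScenarioSet,
    design: SummaryStatDesign,
    samples: dict[str, int],
    n_sim: int,
    n_loci: int = 11,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Simulate ``n_sim`` datasets with scenarios drawn uniformly.

    Returns (scenario_idx, params frame, stats matrix).  Randomness is
    split deterministically: the draw stream comes from ``seed`` and each
    simulation gets its own sub-seed.
    """
    rng = np.random.default_rng(seed)
    names = scenario_set.priors.names
    scenario_idx = np.empty(n_sim, dtype=np.int64)
    params_rows = []
    stats = np.empty((n_sim, len(design.names())))
    for i in range(n_sim):
        k = int(rng.integers(len(scenario_set.templates)))
        template = scenario_set.templates[k]
        feasible = getattr(template.builder, "feasible", None)
        params = scenario_set.priors.sample(rng, feasible=feasible)
        scn = template.build(params)
        sim_seed = int(rng.integers(2**31))
        data = simulate_allele_sizes(scn, samples, n_loci, sim_seed)
        stats[i] = summary_statistics(data, design)
        scenario_idx[i] = k
        params_rows.append(params)
    params_df = pd.DataFrame(params_rows, columns=names)
    return scenario_idx, params_df, stats


def abc_rejection(
    observed: np.ndarray,
    scenario_set: ScenarioSet,
    design: SummaryStatDesign,
    samples: dict[str, int],
    n_sim: int = 20000,
    retain_fraction: float = 0.01,
    n_loci: int = 11,
    seed: int = 0,
    precomputed: tuple | None = None,
) -> ReferenceTable:
    """Simulate (or reuse) a reference table and retain the closest draws.

    Distances are Euclidean on statistics standardized by the simulated
    pool's per-statistic SD; zero-variance statistics are dropped with a
    warning.  ``precomputed`` can carry a (scenario_idx, params, stats)
    triple from :func:`simulate_reference_table` to amortize the table
    across observed vectors.
    """
    if n_sim * retain_fraction < 1:
        raise ValueError("retain_fraction too small for n_sim")
    if precomputed is None:
        scenario_idx, params_df, stats = simulate_reference_table(
            scenario_set, design, samples, n_sim, n_loci, seed
        )
    else:
        scenario_idx, params_df, stats = precomputed
        n_sim = len(scenario_idx)
    sd = stats.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [n for n, k in zip(design.names(), keep) if not k]
        warnings.warn(f"dropping zero-variance statistics: {dropped}")
    sd_safe = np.where(keep, sd, 1.0)
    z = (stats - observed) / sd_safe
    z[:, ~keep] = 0.0
    distances = np.sqrt((z**2).sum(axis=1))
    n_keep = max(int(round(n_sim * retain_fraction)), 1)
    order = np.argsort(distances, kind="stable")
    retained = np.zeros(n_sim, dtype=bool)
    retained[order[:n_keep]] = True
    return ReferenceTable(
        scenario_names=[t.name for t in scenario_set.templates],
        scenario_idx=scenario_idx,
        params=params_df,
        stats=stats,
        stat_names=design.names(),
        observed=np.asarray(observed, dtype=float),
        retained=retained,
        distances=distances,
        stat_sd=sd,
    )


# ---------------------------------------------------------------------------
# Scenario posterior probabilities
# ---------------------------------------------------------------------------


def _proportion_fallback(table: ReferenceTable, note: str) -> dict:
    idx = table.scenario_idx[table.retained]
    n = len(idx)
    out = {}
    for k, name in enumerate(table.scenario_names):
        p = (idx == k).sum() / n
        se = np.sqrt(max(p * (1 - p) / n, 1e-12))
        out[name] = {
            "pp": float(p),
            "ci": (float(max(p - 1.96 * se, 0.0)), float(min(p + 1.96 * se, 1.0))),
            "method": note,
        }
    return out


def model_posterior(table: ReferenceTable) -> dict:
    """Per-scenario posterior probabilities with 95% CIs.

    A multinomial logistic regression of the scenario label on the
    standardized statistics, centered at the observed vector, is
    evaluated at the observed point (the regressors vanish there, so the
    fitted probabilities come from the intercepts).  A mild ridge keeps
    the fit defined under quasi-separation.  CIs propagate the intercept
    covariance (inverse Fisher information at the fit) through the
    softmax; on a failed fit the retained proportions with a binomial CI
    are returned, flagged.
    """
    idx = table.scenario_idx[table.retained]
    present = np.unique(idx)
    if len(present) < 2:
        out = _proportion_fallback(table, "proportion (single scenario retained)")
        return out
    sd_safe = np.where(table.stat_sd > 0, table.stat_sd, 1.0)
    X = (table.stats[table.retained] - table.observed) / sd_safe
    y = idx
    relabel = {k: i for i, k in enumerate(present)}
    y_rel = np.array([relabel[k] for k in y])
    try:
        Zc = X  # statistics centered at the observed point
        from sklearn.linear_model import LogisticRegression

        # mild ridge keeps the fit defined under (quasi-)separation
        clf = LogisticRegression(C=1.0, max_iter=3000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Zc, y_rel)
        pp_by_class = clf.predict_proba(np.zeros((1, Zc.shape[1])))[0]
        pp_present = np.zeros(len(present))
        for cls, p in zip(clf.classes_, pp_by_class):
            pp_present[int(cls)] = p
        if not np.all(np.isfinite(pp_present)):
            raise FloatingPointError("non-finite PP")
        # asymptotic covariance of the coefficients from the Fisher
        # information at the fit (softmax multinomial likelihood)
        D = np.column_stack([np.ones(len(Zc)), Zc])  # (n, d+1)
        P_hat = clf.predict_proba(Zc)  # (n, J) in clf.classes_ order
        order = np.argsort(clf.classes_)
        P_hat = P_hat[:, order]
        J = len(present)
        d1 = D.shape[1]
        info = np.zeros(((J - 1) * d1, (J - 1) * d1))
        for j in range(1, J):
            for m in range(1, J):
                w = P_hat[:, j] * ((j == m) - P_hat[:, m])
                block = D.T @ (D * w[:, None])
                info[(j - 1) * d1 : j * d1, (m - 1) * d1 : m * d1] = block
        cov = np.linalg.pinv(info)
        ipos = [(j - 1) * d1 for j in range(1, J)]  # intercept positions
        cov_int = cov[np.ix_(ipos, ipos)]
        # jacobian of softmax((0, b)) wrt the non-reference intercepts b
        P = pp_present
        jac = np.zeros((J, J - 1))
        for j in range(J):
            for m in range(J - 1):
                jac[j, m] = P[j] * ((1.0 if j == m + 1 else 0.0) - P[m + 1])
        var_pp = np.einsum("jm,mn,jn->j", jac, cov_int, jac)
        se = np.sqrt(np.clip(var_pp, 0.0, None))
    except Exception as exc:  # separation, singularity, non-convergence
        return _proportion_fallback(table, f"proportion (fallback: {exc})")
    out = {}
    for k, name in enumerate(table.scenario_names):
        if k in relabel:
            j = relabel[k]
            p = float(pp_present[j])
            lo = float(np.clip(p - 1.96 * se[j], 0.0, 1.0))
            hi = float(np.clip(p + 1.96 * se[j], 0.0, 1.0))
            out[name] = {"pp": p, "ci": (lo, hi), "method": "lda-logit"}
        else:
            n_ret = len(idx)
            out[name] = {
                "pp": 0.0,
                "ci": (0.0, float(min(3.0 / n_ret, 1.0))),
                "method": "absent from retained set",
            }
    total = sum(v["pp"] for v in out.values())
    for v in out.values():
        v["pp"] /= total
    return out


# ---------------------------------------------------------------------------
# Parameter posteriors
# ---------------------------------------------------------------------------


def _transforms_for(scenario_set: ScenarioSet) -> dict:
    """Parameter -> (forward, backward) regression transforms.

    Sizes and times go to log scale; proportions on [0, 1] to logit.
    """
    from ssrtrace.abc_priors import LogUniform, Uniform

    out = {}
    eps = 1e-9
    for name, marg in scenario_set.priors.marginals.items():
        if isinstance(marg, Uniform) and marg.low >= 0 and marg.high <= 1:
            out[name] = (
                lambda x: np.log((np.clip(x, eps, 1 - eps)) / (1 - np.clip(x, eps, 1 - eps))),
                lambda z: 1.0 / (1.0 + np.exp(-z)),
            )
        else:
            out[name] = (lambda x: np.log(np.maximum(x, eps)), np.exp)
    return out


@dataclass
class ParameterPosterior:
    samples: pd.DataFrame
    quantiles: pd.DataFrame  # rows q2.5 / median / q97.5
    adjusted: bool
    note: str = ""


def parameter_posterior(
    table: ReferenceTable,
    scenario: str,
    scenario_set: ScenarioSet,
    min_retained: int = 200,
) -> ParameterPosterior:
    """Local-linear-regression-adjusted posterior for one scenario.

    Each transformed parameter is regressed on the standardized retained
    statistics and residual-shifted to the observed point (Beaumont
    adjustment); a singular regression falls back to the unadjusted
    rejection posterior, flagged.  Samples violating the scenario's
    structural constraints after adjustment are dropped.
    """
    k = table.scenario_names.index(scenario)
    rows = table.retained & (table.scenario_idx == k)
    if rows.sum() < min_retained:
        raise ValueError(
            f"only {int(rows.sum())} retained simulations of {scenario!r}; "
            f"need >= {min_retained}"
        )
    template = scenario_set.templates[k]
    feasible = getattr(template.builder, "feasible", None)
    params = table.params.loc[rows]
    if template.used_params is not None:
        params = params[[c for c in params.columns if c in template.used_params]]
    params = params.dropna(axis=1)
    sd_safe = np.where(table.stat_sd > 0, table.stat_sd, 1.0)
    S = (table.stats[rows] - table.observed) / sd_safe  # observed -> origin
    transforms = _transforms_for(scenario_set)
    adjusted_cols = {}
    note = ""
    adjusted_flag = True
    X = np.column_stack([np.ones(len(S)), S])
    for name in params.columns:
        fwd, back = transforms[name]
        theta = fwd(params[name].to_numpy())
        try:
            coef, *_ = np.linalg.lstsq(X, theta, rcond=None)
            resid = theta - X @ coef
            adj = coef[0] + resid  # prediction at the observed point + residuals
            adjusted_cols[name] = back(adj)
        except np.linalg.LinAlgError:
            adjusted_cols[name] = params[name].to_numpy()
            adjusted_flag = False
            note = "singular regression: unadjusted rejection posterior"
    samples = pd.DataFrame(adjusted_cols)
    if feasible is not None:
        mask = samples.apply(lambda r: feasible(dict(r)), axis=1).to_numpy()
        if mask.any():
            samples = samples.loc[mask].reset_index(drop=True)
        else:
            note = (note + "; " if note else "") + "no adjusted draw satisfied constraints; unfiltered"
    q = samples.quantile([0.025, 0.5, 0.975])
    return ParameterPosterior(samples=samples, quantiles=q, adjusted=adjusted_flag, note=note)


# ---------------------------------------------------------------------------
# Model checking
# ---------------------------------------------------------------------------


@dataclass
class ModelCheck:
    tail_probabilities: pd.Series  # per-statistic fraction of sims below observed
    overall_fit_percent: float  # % of statistics with tail prob in [0.05, 0.95]
    mahalanobis_sq: float  # observed squared distance in retained PC space
    n_predictive: int


def model_check(
    template: ScenarioTemplate,
    posterior: ParameterPosterior,
    observed: np.ndarray,
    design: SummaryStatDesign,
    samples: dict[str, int],
    n_loci: int = 11,
    n_predictive: int = 200,
    seed: int = 0,
    n_components: int = 5,
) -> ModelCheck:
    """Posterior-predictive check of the selected scenario.

    Simulates datasets at parameter draws from the posterior, reports the
    fraction of simulated values below the observed value per statistic
    (a statistic "fits" when that fraction lies in [0.05, 0.95]), and the
    observed point's squared Mahalanobis distance in the space of the
    first principal components of the simulated statistics.
    """
    if n_predictive < 100:
        raise ValueError("need at least 100 posterior-predictive simulations")
    rng = np.random.default_rng(seed)
    draws = posterior.samples.sample(
        n=n_predictive, replace=True, random_state=int(rng.integers(2**31))
    )
    sims = np.empty((n_predictive, len(design.names())))
    for i, (_, row) in enumerate(draws.iterrows()):
        scn = template.build(dict(row))
        data = simulate_allele_sizes(scn, samples, n_loci, int(rng.integers(2**31)))
        sims[i] = summary_statistics(data, design)
    below = (sims < observed[None, :]).mean(axis=0)
    tails = pd.Series(below, index=design.names())
    fits = ((tails >= 0.05) & (tails <= 0.95)).mean() * 100.0
    from sklearn.decomposition import PCA

    sd = sims.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (sims - sims.mean(axis=0)) / sd_safe
    z_obs = (observed - sims.mean(axis=0)) / sd_safe
    k = min(n_components, Z.shape[1], n_predictive - 1)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(Z)
    obs_scores = pca.transform(z_obs[None, :])[0]
    var = scores.var(axis=0)
    var[var <= 0] = 1.0
    maha = float(((obs_scores**2) / var).sum())
    return ModelCheck(
        tail_probabilities=tails,
        overall_fit_percent=float(fits),
        mahalanobis_sq=maha,
        n_predictive=n_predictive,
    )
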