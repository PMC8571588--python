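"""End-to-end orchestration: statistics -> distances/trees -> ABC stages.

``run_full_pipeline`` reproduces the full analysis graph on either a
user-supplied genotype file or the synthetic study-shaped dataset:
diversity table (with null-corrected He/Fis), null-allele frequencies,
pairwise F_ST (raw and ENA-corrected), NJ trees on Nei and chord
distances, AMOVA, Mantel isolation-by-distance tests, optional Evanno
delta-K post-processing, the staged colonization ABC, and the
mutation-scaled time conversion of the final model's posterior.

Every run writes a resolved-config copy plus a log with seeds and
versions; stages are cached on a config hash so a rerun only recomputes
what changed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import ssrtrace
from ssrtrace import abc as abc_mod
from ssrtrace import scenarios as scn_mod
from ssrtrace.coalescent import generations_to_years
from ssrtrace.distances import (
    geographic_distance_matrix,
    mantel_spearman,
    nei_distance_matrix,
    nj_tree,
    pairwise_fst_matrix,
)
from ssrtrace.diversity import diversity_table, evanno_delta_k, fis
from ssrtrace.genotype_io import GenotypeMatrix, read_genotypes
from ssrtrace.null_alleles import (
    corrected_expected_het,
    estimate_null_alleles,
)
from ssrtrace.synthetic import generate_study_like


@dataclass
class PipelineConfig:
    """Resolved configuration for a full pipeline run."""

    out_dir: str
    input_path: str | None = None  # None -> synthetic study-like dataset
    dialect: str = "genepop"
    seed: int = 20210417
    synthetic_seed: int = 1
    abc_budget: int = 20000
    retain_fraction: float = 0.01
    abc_sample_size: int = 15  # diploids per population in ABC simulations
    rarefaction_genes: int = 160
    mu: float = 3.5e-4
    generation_time_years: float = 2.0
    n_mantel_perm: int = 2000
    n_amova_perm: int = 99
    evanno_loglik_csv: str | None = None
    run_abc: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_dataset(cfg: PipelineConfig) -> GenotypeMatrix:
    if cfg.input_path is None:
        g, truth = generate_study_like(cfg.synthetic_seed)
        return g
    return read_genotypes(cfg.input_path, dialect=cfg.dialect)


def _subsample(g: GenotypeMatrix, per_pop: int, rng: np.random.Generator) -> GenotypeMatrix:
    keep: list[int] = []
    for pop in g.populations:
        rows = np.flatnonzero(g.population == pop)
        if len(rows) > per_pop:
            rows = rng.choice(rows, size=per_pop, replace=False)
        keep.extend(sorted(rows))
    return g.subset(np.array(sorted(keep)))


def _pool_islands(g: GenotypeMatrix, members=("ISA", "FLO"), pooled="ISAFLO") -> GenotypeMatrix:
    pops = g.population.copy()
    pops[np.isin(pops, members)] = pooled
    return GenotypeMatrix(g.individuals, g.loci, g.calls, pops, region=g.region, coords=g.coords)


def _abc_stage(
    g_obs: GenotypeMatrix,
    scenario_set,
    design,
    cfg: PipelineConfig,
    seed: int,
) -> dict:
    observed = abc_mod.summary_statistics(g_obs, design)
    samples = {p: int((g_obs.population == p).sum()) for p in design.populations}
    table = abc_mod.abc_rejection(
        observed,
        scenario_set,
        design,
        samples,
        n_sim=cfg.abc_budget,
        retain_fraction=cfg.retain_fraction,
        seed=seed,
    )
    pps = abc_mod.model_posterior(table)
    best = max(pps, key=lambda k: pps[k]["pp"])
    result = {
        "posterior_probabilities": pps,
        "best_scenario": best,
        "retained_counts": table.retained_counts(),
    }
    k = table.scenario_names.index(best)
    n_best = int((table.retained & (table.scenario_idx == k)).sum())
    if n_best >= 50:
        post = abc_mod.parameter_posterior(
            table, best, scenario_set, min_retained=min(200, n_best)
        )
        result["parameter_quantiles"] = post.quantiles.to_dict()
        result["_posterior"] = post
    result["_table"] = table
    return result


def run_full_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; write outputs under ``cfg.out_dir``; return results."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    t_start = time.time()
    chash = cfg.config_hash()
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))
    results: dict = {"config_hash": chash}

    def stage_seed(name: str) -> int:
        h = int(hashlib.sha256(name.encode()).hexdigest()[:8], 16)
        return int(np.random.SeedSequence((cfg.seed, h)).generate_state(1)[0] % (2**31))

    def stage(name: str):
        """Run a stage, caching its in-memory results keyed on the config
        hash so an interrupted run resumes without recomputation."""

        def wrap(fn):
            import pickle

            t0 = time.time()
            cache = out / f".cache_{name}_{chash}.pkl"
            if cache.exists():
                results.update(pickle.loads(cache.read_bytes()))
                log.append(f"{name}: cached")
                return
            before = set(results)
            fn()
            new = {k: results[k] for k in results if k not in before}
            try:
                cache.write_bytes(pickle.dumps(new))
            except Exception:
                pass  # uncacheable stage results are simply recomputed
            log.append(f"{name}: {time.time() - t0:.2f}s")

        return wrap

    g = _load_dataset(cfg)
    results["n_individuals"] = g.n_individuals
    results["populations"] = {p: int((g.population == p).sum()) for p in g.populations}

    @stage("diversity")
    def _():
        tab = diversity_table(g, rarefaction_genes=cfg.rarefaction_genes)
        est = estimate_null_alleles(g)
        corr_he, corr_fis = {}, {}
        for pop in g.populations:
            he_c = corrected_expected_het(est, g, pop)
            corr_he[pop] = he_c
            corr_fis[pop] = fis(tab.loc[pop, "Ho"], he_c)
        tab["He_corrected"] = pd.Series(corr_he)
        tab["Fis_corrected"] = pd.Series(corr_fis)
        tab.to_csv(out / "diversity_table.csv")
        est.beta_table().to_csv(out / "null_allele_beta.csv")
        results["diversity"] = tab
        results["null_estimates"] = est
        results["mean_null_beta"] = est.mean_beta()

    est = results["null_estimates"]

    @stage("distances")
    def _():
        fst = pairwise_fst_matrix(g)
        fst_ena = pairwise_fst_matrix(g, correction="ena", est=est)
        fst.to_frame().to_csv(out / "fst_pairwise.csv")
        fst_ena.to_frame().to_csv(out / "fst_pairwise_ena.csv")
        nei = nei_distance_matrix(g)
        tree = nj_tree(nei) if len(nei.labels) >= 3 else None
        if tree is not None:
            (out / "nj_nei.nwk").write_text(str(tree))
        from ssrtrace.distances import chord_distance_matrix

        dch_dm = chord_distance_matrix(g, ina_correction=True)
        dch_dm.to_frame().to_csv(out / "dch_pairwise.csv")
        dch_dm.to_phylip(out / "dch_pairwise.phy")
        if len(dch_dm.labels) >= 3:
            (out / "nj_dch.nwk").write_text(str(nj_tree(dch_dm)))
        results["fst"] = fst
        results["fst_ena"] = fst_ena
        results["nei"] = nei
        results["dch"] = dch_dm

    @stage("mantel")
    def _():
        if g.coords is None:
            results["mantel"] = None
            return
        nei = results["nei"]
        geo = geographic_distance_matrix(g)
        if len(geo.labels) >= 4 and geo.labels == nei.labels:
            res = mantel_spearman(
                geo, nei, n_perm=cfg.n_mantel_perm, seed=stage_seed("mantel")
            )
            results["mantel"] = {"rho": res.statistic, "p": res.p_value}
        else:
            results["mantel"] = None
        if results["mantel"] is not None:
            (out / "mantel.json").write_text(json.dumps(results["mantel"], indent=2))

    @stage("amova")
    def _():
        from ssrtrace.distances import amova

        res = amova(g, n_perm=cfg.n_amova_perm, seed=stage_seed("amova"))
        frame = pd.DataFrame(
            {
                "percent_variation": res.percentages,
                "p_value": res.p_values,
                "df": res.df,
            }
        )
        frame.to_csv(out / "amova.csv")
        results["amova"] = res

    @stage("evanno")
    def _():
        if cfg.evanno_loglik_csv is None:
            results["evanno"] = None
            return
        table = pd.read_csv(cfg.evanno_loglik_csv)
        ev = evanno_delta_k(table)
        ev.to_csv(out / "evanno.csv", index=False)
        results["evanno"] = {"best_k": ev.attrs["best_k"]}

    if cfg.run_abc:

        @stage("abc_stage1")
        def _():
            rng1 = np.random.default_rng(stage_seed("abc_stage1"))
            sub = _subsample(g, cfg.abc_sample_size, rng1)
            pooled = _pool_islands(sub)
            ss = scn_mod.stage1_scenarios()
            design = abc_mod.SummaryStatDesign.full(
                [scn_mod.MAINLAND, scn_mod.SCY, scn_mod.ISAFLO, scn_mod.SCZ],
                trios=[(scn_mod.SCZ, scn_mod.SCY, scn_mod.ISAFLO)],
            )
            res = _abc_stage(pooled, ss, design, cfg, seed=stage_seed("abc_stage1_table"))
            results["abc_stage1"] = res
            (out / "abc_stage1.json").write_text(
                json.dumps({k: v for k, v in res.items() if not k.startswith("_")},
                           indent=2, default=str)
            )

        @stage("abc_stage2")
        def _():
            rng2 = np.random.default_rng(stage_seed("abc_stage2"))
            sub = _subsample(g, cfg.abc_sample_size, rng2)
            keep = np.isin(sub.population, [scn_mod.MAINLAND, scn_mod.SCY, scn_mod.ISA, scn_mod.FLO])
            sub = sub.subset(keep)
            ss = scn_mod.stage2_scenarios()
            design = abc_mod.SummaryStatDesign.full(
                [scn_mod.MAINLAND, scn_mod.SCY, scn_mod.ISA, scn_mod.FLO]
            )
            res = _abc_stage(sub, ss, design, cfg, seed=stage_seed("abc_stage2_table"))
            results["abc_stage2"] = res
            (out / "abc_stage2.json").write_text(
                json.dumps({k: v for k, v in res.items() if not k.startswith("_")},
                           indent=2, default=str)
            )

        @stage("abc_final")
        def _():
            rng3 = np.random.default_rng(stage_seed("abc_final"))
            sub = _subsample(g, cfg.abc_sample_size, rng3)
            ss = scn_mod.final_model()
            design = abc_mod.SummaryStatDesign.full(
                [scn_mod.MAINLAND, scn_mod.SCY, scn_mod.ISA, scn_mod.FLO, scn_mod.SCZ],
                trios=[(scn_mod.SCZ, scn_mod.SCY, scn_mod.ISA)],
            )
            res = _abc_stage(sub, ss, design, cfg, seed=stage_seed("abc_final_table"))
            results["abc_final"] = res
            (out / "abc_final.json").write_text(
                json.dumps({k: v for k, v in res.items() if not k.startswith("_")},
                           indent=2, default=str)
            )
            post = res.get("_posterior")
            if post is not None:
                times = {}
                for t_name in ("t1", "t2", "t3", "t4"):
                    if t_name in post.quantiles.columns:
                        med = float(post.quantiles.loc[0.5, t_name])
                        times[t_name] = {
                            "generations": int(round(med)),
                            "years_min": generations_to_years(
                                med, cfg.generation_time_years
                            ),
                        }
                results["time_estimates"] = times
                (out / "time_estimates.json").write_text(json.dumps(times, indent=2))

    log.append(f"total: {time.time() - t_start:.2f}s")
    (out / "run.log").write_text(
        "\n".join(
            [f"ssrtrace {ssrtrace.__version__}", f"seed {cfg.seed}", *log]
        )
        + "\n"
    )
    return results
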