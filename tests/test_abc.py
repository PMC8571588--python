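"""ABC engine: summary statistics, rejection, posteriors, model check.

The heavier scenario-recovery and admixture-recovery experiments at the
full 20,000-simulation budget live in the acceptance suite; here the
machinery is exercised at reduced scale.
"""

import numpy as np
import pytest

from ssrtrace.abc import (
    ReferenceTable,
    SummaryStatDesign,
    abc_rejection,
    model_check,
    model_posterior,
    parameter_posterior,
    pop_locus_arrays,
    simulate_reference_table,
    summary_statistics,
)
from ssrtrace.coalescent import DemographicScenario, Merge, simulate_allele_sizes
from ssrtrace.genotype_io import GenotypeMatrix
from ssrtrace.scenarios import ScenarioSet, ScenarioTemplate, stage2_scenarios
from ssrtrace.abc_priors import PriorSpec, Uniform, LogUniform


def _two_pop_design():
    return SummaryStatDesign.full(["A", "B"])


class TestSummaryStatistics:
    def test_identical_populations(self):
        rng = np.random.default_rng(0)
        pool = rng.integers(10, 16, size=(40, 11))
        data = {"A": pool, "B": pool.copy()}
        design = _two_pop_design()
        v = dict(zip(design.names(), summary_statistics(data, design)))
        # W&C theta is unbiased, so identical samples give a value near
        # zero (slightly negative by construction)
        assert v["fst_A-B"] == pytest.approx(0.0, abs=0.05)
        assert v["dm2_A-B"] == 0.0
        assert v["nal_A"] == v["nal_B"]

    def test_dm2_hand_computed(self):
        data = {"A": np.full((4, 1), 10), "B": np.full((4, 1), 13)}
        design = SummaryStatDesign(["A", "B"], pairs=[("A", "B")], per_pair=("dm2",))
        assert summary_statistics(data, design)[-1] == 9.0

    def test_das_bounds_and_identical_individuals(self):
        data = {"A": np.full((6, 3), 12), "B": np.full((6, 3), 12)}
        design = SummaryStatDesign(["A", "B"], pairs=[("A", "B")], per_pair=("das",))
        assert summary_statistics(data, design)[-1] == pytest.approx(0.0)
        data2 = {"A": np.full((6, 3), 12), "B": np.full((6, 3), 19)}
        assert summary_statistics(data2, design)[-1] == pytest.approx(1.0)

    def test_admixture_alpha_boundary(self):
        rng = np.random.default_rng(1)
        p1 = rng.integers(10, 14, size=(30, 5))
        p2 = p1 + 10  # disjoint
        design = SummaryStatDesign(
            ["adm", "P1", "P2"], pairs=[], trios=[("adm", "P1", "P2")],
            per_population=("nal",),
        )
        v = summary_statistics({"adm": p1.copy(), "P1": p1, "P2": p2}, design)
        assert v[-1] == pytest.approx(1.0, abs=0.01)
        v2 = summary_statistics({"adm": p2.copy(), "P1": p1, "P2": p2}, design)
        assert v2[-1] == pytest.approx(0.0, abs=0.01)

    def test_genotype_matrix_and_array_inputs_agree(self):
        scn = DemographicScenario("two", {"A": 500.0, "B": 500.0}, [Merge("B", "A", 300.0)])
        data = simulate_allele_sizes(scn, {"A": 10, "B": 10}, 5, seed=4)
        from ssrtrace.coalescent import simulate_dataset

        g = simulate_dataset(scn, {"A": 10, "B": 10}, 5, seed=4)
        design = _two_pop_design()
        va = summary_statistics(data, design)
        vg = summary_statistics(g, design)
        assert va == pytest.approx(vg)

    def test_empty_population_rejected(self):
        design = _two_pop_design()
        with pytest.raises(ValueError):
            summary_statistics({"A": np.empty((0, 3), dtype=int), "B": np.full((4, 3), 1)}, design)


def _toy_scenario_set():
    """Two well-separated one-population scenarios (size 100 vs 5000)."""

    def build_small(params):
        return DemographicScenario("small", {"A": params["n_small"], "B": params["n_small"]},
                                   [Merge("B", "A", params["t"])])

    def build_big(params):
        return DemographicScenario("big", {"A": params["n_big"], "B": params["n_big"]},
                                   [Merge("B", "A", params["t"])])

    priors = PriorSpec(
        {
            "n_small": LogUniform(50, 200),
            "n_big": LogUniform(5000, 20000),
            "t": Uniform(50, 200),
        }
    )
    templates = [
        ScenarioTemplate("small", "tiny populations", build_small),
        ScenarioTemplate("big", "large populations", build_big),
    ]
    return ScenarioSet("toy", templates, priors)


class TestRejection:
    def test_retain_all_returns_full_table(self):
        ss = _toy_scenario_set()
        design = _two_pop_design()
        samples = {"A": 8, "B": 8}
        obs = np.zeros(len(design.names()))
        table = abc_rejection(obs, ss, design, samples, n_sim=40, retain_fraction=1.0, seed=1)
        assert table.retained.all()

    def test_table_frame_export(self):
        ss = _toy_scenario_set()
        design = _two_pop_design()
        samples = {"A": 6, "B": 6}
        obs = np.zeros(len(design.names()))
        table = abc_rejection(obs, ss, design, samples, n_sim=20, retain_fraction=0.2, seed=3)
        frame = table.to_frame()
        assert len(frame) == 20
        assert {"scenario", "distance", "retained"} <= set(frame.columns)
        assert frame["retained"].sum() == 4

    def test_deterministic_given_seed(self):
        ss = _toy_scenario_set()
        design = _two_pop_design()
        samples = {"A": 8, "B": 8}
        obs = np.zeros(len(design.names()))
        t1 = abc_rejection(obs, ss, design, samples, n_sim=30, retain_fraction=0.2, seed=9)
        t2 = abc_rejection(obs, ss, design, samples, n_sim=30, retain_fraction=0.2, seed=9)
        assert np.array_equal(t1.stats, t2.stats)
        assert np.array_equal(t1.retained, t2.retained)
        assert t1.params.equals(t2.params)

    def test_true_scenario_enriched_among_retained(self):
        ss = _toy_scenario_set()
        design = _two_pop_design()
        samples = {"A": 10, "B": 10}
        pre = simulate_reference_table(ss, design, samples, n_sim=400, n_loci=8, seed=3)
        rng = np.random.default_rng(11)
        t = ss.templates[0]  # "small"
        data = simulate_allele_sizes(
            t.build(ss.priors.sample(rng)), samples, 8, seed=77
        )
        obs = summary_statistics(data, design)
        table = abc_rejection(obs, ss, design, samples, retain_fraction=0.1,
                              precomputed=pre)
        counts = table.retained_counts()
        assert counts["small"] > 2 * counts["big"]


class TestModelPosterior:
    def _table(self, obs_from="small", n_sim=400):
        ss = _toy_scenario_set()
        design = _two_pop_design()
        samples = {"A": 10, "B": 10}
        pre = simulate_reference_table(ss, design, samples, n_sim=n_sim, n_loci=8, seed=5)
        rng = np.random.default_rng(2)
        t = ss.templates[0 if obs_from == "small" else 1]
        data = simulate_allele_sizes(t.build(ss.priors.sample(rng)), samples, 8, seed=21)
        obs = summary_statistics(data, design)
        return ss, abc_rejection(obs, ss, design, samples, retain_fraction=0.1,
                                 precomputed=pre)

    def test_pp_normalized_and_true_scenario_wins(self):
        ss, table = self._table("small")
        pps = model_posterior(table)
        total = sum(v["pp"] for v in pps.values())
        assert total == pytest.approx(1.0, abs=0.01)
        assert pps["small"]["pp"] > pps["big"]["pp"]
        for v in pps.values():
            assert v["ci"][0] <= v["pp"] <= v["ci"][1]

    def test_absent_scenario_near_zero(self):
        ss = _toy_scenario_set()
        design = _two_pop_design()
        # craft a retained table where scenario 1 never appears
        n = 60
        stats = np.random.default_rng(0).normal(size=(n, len(design.names())))
        table = ReferenceTable(
            scenario_names=["small", "big"],
            scenario_idx=np.zeros(n, dtype=np.int64),
            params=__import__("pandas").DataFrame({"n_small": np.ones(n)}),
            stats=stats,
            stat_names=design.names(),
            observed=np.zeros(len(design.names())),
            retained=np.ones(n, dtype=bool),
            distances=np.zeros(n),
            stat_sd=np.ones(len(design.names())),
        )
        pps = model_posterior(table)
        assert pps["big"]["pp"] == pytest.approx(0.0, abs=1e-9)
        assert pps["big"]["ci"][1] < 0.1


class TestParameterPosterior:
    def test_adjustment_tightens_posterior(self):
        ss = _toy_scenario_set()
        design = _two_pop_design()
        samples = {"A": 10, "B": 10}
        pre = simulate_reference_table(ss, design, samples, n_sim=500, n_loci=8, seed=8)
        scenario_idx, params_df, stats = pre
        # observed = one simulated vector from the table, drawn from the
        # "small" scenario
        obs = stats[np.flatnonzero(scenario_idx == 0)[3]]
        table = abc_rejection(obs, ss, design, samples, retain_fraction=0.3,
                              precomputed=pre)
        tighter = 0
        post = parameter_posterior(table, "small", ss, min_retained=20)
        rows = table.retained & (table.scenario_idx == 0)
        raw = table.params.loc[rows, "t"]
        adj = post.samples["t"]
        assert adj.var() <= raw.var() * 1.5  # adjustment should not blow up
        assert post.samples.columns.tolist() == ["n_small", "t"]

    def test_too_few_retained_rejected(self):
        ss = _toy_scenario_set()
        design = _two_pop_design()
        samples = {"A": 6, "B": 6}
        obs = np.zeros(len(design.names()))
        table = abc_rejection(obs, ss, design, samples, n_sim=30, retain_fraction=0.3, seed=2)
        with pytest.raises(ValueError):
            parameter_posterior(table, "small", ss, min_retained=200)


class TestModelCheck:
    def test_self_consistency_and_extreme_misfit(self):
        ss = _toy_scenario_set()
        design = _two_pop_design()
        samples = {"A": 8, "B": 8}
        pre = simulate_reference_table(ss, design, samples, n_sim=300, n_loci=8, seed=12)
        rng = np.random.default_rng(4)
        t = ss.templates[1]
        data = simulate_allele_sizes(t.build(ss.priors.sample(rng)), samples, 8, seed=31)
        obs = summary_statistics(data, design)
        table = abc_rejection(obs, ss, design, samples, retain_fraction=0.2,
                              precomputed=pre)
        post = parameter_posterior(table, "big", ss, min_retained=15)
        mc = model_check(t, post, obs, design, samples, n_loci=8,
                         n_predictive=100, seed=0)
        assert ((mc.tail_probabilities >= 0) & (mc.tail_probabilities <= 1)).all()
        assert mc.overall_fit_percent >= 50.0
        mc_bad = model_check(t, post, obs * 10 + 50, design, samples, n_loci=8,
                             n_predictive=100, seed=0)
        assert mc_bad.overall_fit_percent <= 20.0
        assert mc_bad.mahalanobis_sq > mc.mahalanobis_sq

    def test_minimum_predictive_simulations(self):
        ss = _toy_scenario_set()
        with pytest.raises(ValueError):
            model_check(ss.templates[0], None, None, None, None, n_predictive=50)
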