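"""Declarative colonization-scenario sets for the island-invasion ABC.

Three analysis stages are encoded:

* origin analysis — which of five structured mainland lineages (or which
  admixed pair) seeded a given island lineage: 5 single-origin plus
  C(5,2) = 10 admixture scenarios;
* stage 1 — 16 colonization topologies over {Mainland, SCY, ISA/FLO, SCZ}
  with the Isabela/Floreana group treated as one population and no
  scenario deriving SCY or ISA/FLO from SCZ;
* stage 2 — 9 topologies separating Floreana and Isabela, including
  Floreana-first, Isabela-first, parallel-introduction and
  Floreana-before-all variants;
* the final model — Mainland -> SCY (t4), SCY -> FLO (t3), FLO -> ISA
  (t2), SCY -> SCZ (t1) with t4 > t3 > t2 > t1 and a founder bottleneck
  at every introduction.

Only the scenarios named in the source analyses are pinned; the remaining
members of the 16- and 9-scenario sets are systematic completions over
the allowed source relations and are flagged as reconstructions in their
descriptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import yaml

from ssrtrace.abc_priors import PriorSpec, Uniform, LogUniform
from ssrtrace.coalescent import (
    Admix,
    DemographicScenario,
    Merge,
    SizeChange,
)

MAINLAND = "Mainland"
SCY = "SCY"  # San Cristobal
SCZ = "SCZ"  # Santa Cruz
ISA = "ISA"  # Isabela
FLO = "FLO"  # Floreana
ISAFLO = "ISAFLO"  # Isabela + Floreana treated as one group (stage 1)

MUTATION_RATE = 3.5e-4  # per locus per generation, plant SSR scale


@dataclass
class ScenarioTemplate:
    """A topology whose numeric parameters are drawn from a PriorSpec.

    ``build(params)`` instantiates a concrete
    :class:`~ssrtrace.coalescent.DemographicScenario`.
    """

    name: str
    description: str
    builder: object  # callable params-dict -> DemographicScenario
    reconstruction: bool = False
    used_params: tuple[str, ...] | None = None  # recorded on first build

    def build(self, params: dict) -> DemographicScenario:
        if self.used_params is None:
            accessed: set[str] = set()

            class _Recorder(dict):
                def __getitem__(self, key):
                    accessed.add(key)
                    return dict.__getitem__(self, key)

            scn = self.builder(_Recorder(params))
            feasible = getattr(self.builder, "feasible", None)
            if feasible is not None:
                feasible(_Recorder(params))
            self.used_params = tuple(sorted(accessed))
        else:
            scn = self.builder(params)
        scn.validate()
        return scn


@dataclass
class ScenarioSet:
    """A named list of scenario templates sharing one prior specification."""

    name: str
    templates: list[ScenarioTemplate]
    priors: PriorSpec
    note: str = ""

    def __len__(self) -> int:
        return len(self.templates)

    def to_yaml(self) -> str:
        payload = {
            "name": self.name,
            "note": self.note,
            "priors": self.priors.to_dict(),
            "scenarios": [
                {"name": t.name, "description": t.description,
                 "reconstruction": t.reconstruction}
                for t in self.templates
            ],
        }
        return yaml.safe_dump(payload, sort_keys=False)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _island_intro(pop: str, source: str, t: float, n_founder: float, bottleneck: float) -> list:
    start = max(t - bottleneck, 0.0)
    return [SizeChange(pop, start, n_founder), Merge(pop, source, t)]


def _ordered(params: dict, keys: list[str]) -> bool:
    vals = [params[k] for k in keys]
    return all(a > b for a, b in zip(vals, vals[1:]))


# ---------------------------------------------------------------------------
# Stage 1: 16 scenarios over {Mainland, SCY, ISAFLO, SCZ}
# ---------------------------------------------------------------------------

# acyclic source combinations for (SCY, ISA/FLO); "admix" for ISA/FLO is a
# dual introduction: admixture of Mainland and SCY stock
_STAGE1_BACKBONES = (
    (MAINLAND, MAINLAND),
    (MAINLAND, SCY),
    (MAINLAND, "admix"),
    (ISAFLO, MAINLAND),
)
_STAGE1_SOURCES_SCZ = (MAINLAND, SCY, ISAFLO, "admix")


def _stage1_builder(src_scy: str, src_isaflo: str, src_scz: str):
    def build(params: dict) -> DemographicScenario:
        pops = {
            MAINLAND: params["n_mainland"],
            SCY: params["n_scy"],
            ISAFLO: params["n_isaflo"],
            SCZ: params["n_scz"],
        }
        bott = params["bottleneck_duration"]
        events: list = []
        t = {SCY: params["t_scy"], ISAFLO: params["t_isaflo"], SCZ: params["t_scz"]}
        events += _island_intro(SCY, src_scy, t[SCY], params["n_found_scy"], bott)
        if src_isaflo == "admix":
            events.append(SizeChange(ISAFLO, max(t[ISAFLO] - bott, 0.0), params["n_found_isaflo"]))
            events.append(Admix(ISAFLO, MAINLAND, SCY, t[ISAFLO], params["r_isaflo"]))
        else:
            events += _island_intro(ISAFLO, src_isaflo, t[ISAFLO], params["n_found_isaflo"], bott)
        if src_scz == "admix":
            events.append(SizeChange(SCZ, max(t[SCZ] - bott, 0.0), params["n_found_scz"]))
            events.append(Admix(SCZ, SCY, ISAFLO, t[SCZ], params["r_scz"]))
        else:
            events += _island_intro(SCZ, src_scz, t[SCZ], params["n_found_scz"], bott)
        return DemographicScenario(
            name="stage1", populations=pops, events=events, mutation_rate=MUTATION_RATE
        )

    def feasible(params: dict) -> bool:
        t = {SCY: params["t_scy"], ISAFLO: params["t_isaflo"],
             SCZ: params["t_scz"], MAINLAND: float("inf")}
        if t[SCY] >= t[src_scy]:
            return False
        if src_isaflo == "admix":
            if t[ISAFLO] >= t[SCY]:
                return False
        elif t[ISAFLO] >= t[src_isaflo]:
            return False
        if src_scz == "admix":
            if t[SCZ] >= min(t[SCY], t[ISAFLO]):
                return False
        elif t[SCZ] >= t[src_scz]:
            return False
        return True

    build.feasible = feasible
    return build


def stage1_scenarios() -> ScenarioSet:
    """16 colonization topologies over {Mainland, SCY, ISA/FLO, SCZ}.

    Systematic completion: four acyclic backbones for (SCY, ISA/FLO) —
    both from the mainland, ISA/FLO from SCY, ISA/FLO as a dual
    Mainland x SCY introduction, or SCY from ISA/FLO — crossed with four
    sources for SCZ ({Mainland, SCY, ISA/FLO, SCY x ISA/FLO admixture}).
    No scenario derives SCY or ISA/FLO from SCZ.  Includes the
    best-supported topology (Mainland -> SCY -> {ISA/FLO, SCZ}) and the
    runner-up (SCZ as a SCY x ISA/FLO admixture); the rest are flagged as
    reconstructions.
    """
    priors = PriorSpec(
        {
            "n_mainland": LogUniform(1000, 100000),
            "n_scy": LogUniform(10, 10000),
            "n_isaflo": LogUniform(10, 10000),
            "n_scz": LogUniform(10, 10000),
            "n_found_scy": LogUniform(2, 100),
            "n_found_isaflo": LogUniform(2, 100),
            "n_found_scz": LogUniform(2, 100),
            "t_scy": Uniform(10, 2000),
            "t_isaflo": Uniform(10, 2000),
            "t_scz": Uniform(10, 2000),
            "bottleneck_duration": Uniform(2, 50),
            "r_scz": Uniform(0, 1),
            "r_isaflo": Uniform(0, 1),
        }
    )
    templates = []
    named_best = (MAINLAND, SCY, SCY)
    named_second = (MAINLAND, SCY, "admix")
    for src_scy, src_isaflo in _STAGE1_BACKBONES:
        for src_scz in _STAGE1_SOURCES_SCZ:
            combo = (src_scy, src_isaflo, src_scz)
            if_desc = (
                "Mainland x SCY admixture" if src_isaflo == "admix" else src_isaflo
            )
            desc = (
                f"SCY from {src_scy}; ISA/FLO from {if_desc}; "
                f"SCZ from {'SCY x ISA/FLO admixture' if src_scz == 'admix' else src_scz}"
            )
            templates.append(
                ScenarioTemplate(
                    name=f"S1-{len(templates) + 1:02d}",
                    description=desc,
                    builder=_stage1_builder(*combo),
                    reconstruction=combo not in (named_best, named_second),
                )
            )
    return ScenarioSet(
        "stage1",
        templates,
        priors,
        note="whole mainland as the source; ISA and FLO pooled; SCZ never ancestral to SCY or ISA/FLO",
    )


# ---------------------------------------------------------------------------
# Stage 2: 9 scenarios over {Mainland, SCY, FLO, ISA}
# ---------------------------------------------------------------------------

#: (ISA source, FLO source, SCY source); "t" keys are per-island split times.
_STAGE2_TOPOLOGIES: list[tuple[str, str, str, str, bool]] = [
    # name, isa_src, flo_src, scy_src, reconstruction?
    ("S2-1", SCY, ISA, MAINLAND, True),   # SCY -> ISA -> FLO
    ("S2-2", SCY, SCY, MAINLAND, True),   # both islands directly from SCY
    ("S2-3", MAINLAND, SCY, MAINLAND, True),  # parallel mainland intro to ISA
    ("S2-4", FLO, SCY, MAINLAND, False),  # SCY -> FLO -> ISA (best supported)
    ("S2-5", SCY, MAINLAND, MAINLAND, True),  # parallel mainland intro to FLO
    ("S2-6", MAINLAND, MAINLAND, MAINLAND, True),  # both parallel from mainland
    ("S2-7", FLO, MAINLAND, FLO, True),   # Floreana first, seeds SCY and ISA
    ("S2-8", SCY, MAINLAND, FLO, True),   # Floreana first from mainland, then SCY
    ("S2-9", MAINLAND, ISA, MAINLAND, True),  # ISA from mainland, seeds FLO
]


def _stage2_builder(isa_src: str, flo_src: str, scy_src: str):
    def build(params: dict) -> DemographicScenario:
        pops = {
            MAINLAND: params["n_mainland"],
            SCY: params["n_scy"],
            ISA: params["n_isa"],
            FLO: params["n_flo"],
        }
        bott = params["bottleneck_duration"]
        events: list = []
        for child, src in ((ISA, isa_src), (FLO, flo_src), (SCY, scy_src)):
            events += _island_intro(
                child, src, params[f"t_{child.lower()}"],
                params[f"n_found_{child.lower()}"], bott,
            )
        return DemographicScenario(
            name="stage2", populations=pops, events=events, mutation_rate=MUTATION_RATE
        )

    def feasible(params: dict) -> bool:
        t = {ISA: params["t_isa"], FLO: params["t_flo"],
             SCY: params["t_scy"], MAINLAND: float("inf")}
        for child, src in ((ISA, isa_src), (FLO, flo_src), (SCY, scy_src)):
            if t[child] >= t[src]:
                return False
        return True

    build.feasible = feasible
    return build


def stage2_scenarios() -> ScenarioSet:
    """9 topologies separating Floreana and Isabela.

    The named best topology (S2-4: SCY -> FLO -> ISA) is joined by
    Isabela-first, direct-from-SCY, parallel-mainland-introduction and
    Floreana-before-all reconstructions.
    """
    priors = PriorSpec(
        {
            "n_mainland": LogUniform(1000, 100000),
            "n_scy": LogUniform(10, 10000),
            "n_isa": LogUniform(10, 10000),
            "n_flo": LogUniform(10, 10000),
            "n_found_scy": LogUniform(2, 100),
            "n_found_isa": LogUniform(2, 100),
            "n_found_flo": LogUniform(2, 100),
            "t_scy": Uniform(10, 2000),
            "t_isa": Uniform(10, 2000),
            "t_flo": Uniform(10, 2000),
            "bottleneck_duration": Uniform(2, 50),
        }
    )
    templates = [
        ScenarioTemplate(
            name=name,
            description=f"ISA from {isa}; FLO from {flo}; SCY from {scy}",
            builder=_stage2_builder(isa, flo, scy),
            reconstruction=recon,
        )
        for name, isa, flo, scy, recon in _STAGE2_TOPOLOGIES
    ]
    return ScenarioSet(
        "stage2",
        templates,
        priors,
        note="SCZ excluded; Floreana and Isabela separated to order their introductions",
    )


# ---------------------------------------------------------------------------
# Origin analysis: 15 scenarios over 5 mainland lineages + one island lineage
# ---------------------------------------------------------------------------

DEFAULT_MAINLAND_LINEAGES = (
    "NorthernCoastal",
    "Amazonian",
    "Central",
    "Southern",
    "Dispersed",
)


def _origin_builder(target: str, lineages: tuple, source_a: str, source_b: str | None):
    def build(params: dict) -> DemographicScenario:
        pops = {lin: params[f"n_{lin}"] for lin in lineages}
        pops[target] = params["n_target"]
        events: list = []
        # serial divergence of the mainland lineages from a shared stock
        for i, lin in enumerate(lineages[1:], start=1):
            events.append(Merge(lin, lineages[0], params["t_mainland"] + i))
        bott = params["bottleneck_duration"]
        t0 = params["t_target"]
        events.append(SizeChange(target, max(t0 - bott, 0.0), params["n_found_target"]))
        if source_b is None:
            events.append(Merge(target, source_a, t0))
        else:
            events.append(Admix(target, source_a, source_b, t0, params["r_target"]))
        return DemographicScenario(
            name="origin", populations=pops, events=events, mutation_rate=MUTATION_RATE
        )

    def feasible(params: dict) -> bool:
        return params["t_target"] < params["t_mainland"]

    build.feasible = feasible
    return build


def origin_scenarios(
    target: str = "IslandLineage",
    mainland_lineages: tuple = DEFAULT_MAINLAND_LINEAGES,
) -> ScenarioSet:
    """5 single-origin + 10 pairwise-admixture origin scenarios.

    ``target`` names the island lineage under test (the Isabela/Floreana
    or the San Cristobal lineage); each scenario derives it either from a
    single mainland lineage or from the admixture of one of the C(5,2)
    lineage pairs.
    """
    if len(mainland_lineages) != 5:
        raise ValueError("exactly 5 mainland source lineages are required")
    priors_dict: dict = {f"n_{lin}": LogUniform(500, 50000) for lin in mainland_lineages}
    priors_dict.update(
        {
            "n_target": LogUniform(10, 10000),
            "n_found_target": LogUniform(2, 100),
            "t_target": Uniform(10, 2000),
            "t_mainland": Uniform(2000, 20000),
            "bottleneck_duration": Uniform(2, 50),
            "r_target": Uniform(0, 1),
        }
    )
    priors = PriorSpec(priors_dict)
    templates = []
    for lin in mainland_lineages:
        templates.append(
            ScenarioTemplate(
                name=f"origin-{lin}",
                description=f"{target} from {lin} alone",
                builder=_origin_builder(target, mainland_lineages, lin, None),
            )
        )
    for a, b in combinations(mainland_lineages, 2):
        templates.append(
            ScenarioTemplate(
                name=f"origin-{a}x{b}",
                description=f"{target} from the admixture of {a} and {b}",
                builder=_origin_builder(target, mainland_lineages, a, b),
            )
        )
    return ScenarioSet("origin", templates, priors, note=f"origin of {target}")


# ---------------------------------------------------------------------------
# Final model
# ---------------------------------------------------------------------------


def final_model() -> ScenarioSet:
    """The final four-island colonization model as a one-template set.

    Mainland -> SCY at t4, SCY -> FLO at t3, FLO -> ISA at t2 and
    SCY -> SCZ at t1 with t4 > t3 > t2 > t1 and a founder bottleneck at
    every introduction.
    """

    def build(params: dict) -> DemographicScenario:
        pops = {
            MAINLAND: params["n_mainland"],
            SCY: params["n_scy"],
            FLO: params["n_flo"],
            ISA: params["n_isa"],
            SCZ: params["n_scz"],
        }
        bott = params["bottleneck_duration"]
        events = (
            _island_intro(SCZ, SCY, params["t1"], params["n_found_scz"], bott)
            + _island_intro(ISA, FLO, params["t2"], params["n_found_isa"], bott)
            + _island_intro(FLO, SCY, params["t3"], params["n_found_flo"], bott)
            + _island_intro(SCY, MAINLAND, params["t4"], params["n_found_scy"], bott)
        )
        return DemographicScenario(
            name="final", populations=pops, events=events, mutation_rate=MUTATION_RATE
        )

    def feasible(params: dict) -> bool:
        return _ordered(params, ["t4", "t3", "t2", "t1"])

    build.feasible = feasible
    priors = PriorSpec(
        {
            "n_mainland": LogUniform(1000, 100000),
            "n_scy": LogUniform(10, 10000),
            "n_flo": LogUniform(10, 10000),
            "n_isa": LogUniform(10, 10000),
            "n_scz": LogUniform(10, 10000),
            "n_found_scy": LogUniform(2, 100),
            "n_found_flo": LogUniform(2, 100),
            "n_found_isa": LogUniform(2, 100),
            "n_found_scz": LogUniform(2, 100),
            "t1": Uniform(5, 500),
            "t2": Uniform(10, 1000),
            "t3": Uniform(20, 1500),
            "t4": Uniform(100, 2500),
            "bottleneck_duration": Uniform(2, 50),
        }
    )
    template = ScenarioTemplate(
        name="final",
        description="Mainland -> SCY (t4); SCY -> FLO (t3); FLO -> ISA (t2); SCY -> SCZ (t1)",
        builder=build,
    )
    return ScenarioSet("final", [template], priors, note="staged four-island colonization")
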