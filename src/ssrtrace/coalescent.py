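"""Backward-in-time coalescent simulator for unlinked SSR loci.

Demography is an event list over named populations: population merges
(splits, viewed forward in time), two-parent admixtures, instantaneous
size changes (founder bottlenecks), and optional continuous migration.
Time is measured in generations, sizes are diploid effective sizes, and
mutation follows the strict single-step stepwise model (SMM): each
mutation shifts the allele repeat count by +-1 with equal probability.

The continuous-time approximation is used throughout: within a population
of size N holding k lineages, the next coalescence is exponential with
rate k(k-1)/2 / (2N) per generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ssrtrace.genotype_io import MISSING, GenotypeMatrix


class ScenarioValidationError(ValueError):
    """Raised when a demographic scenario cannot deliver all lineages to a
    single common ancestor."""


@dataclass(frozen=True)
class SizeChange:
    population: str
    time: float
    size: float


@dataclass(frozen=True)
class Merge:
    """Backward in time, all lineages of ``child`` move into ``parent``
    at ``time`` (forward in time: ``child`` splits off ``parent``)."""

    child: str
    parent: str
    time: float


@dataclass(frozen=True)
class Admix:
    """Backward in time, each lineage of ``child`` moves to ``parent_a``
    with probability ``prop_a`` and otherwise to ``parent_b``."""

    child: str
    parent_a: str
    parent_b: str
    time: float
    prop_a: float


@dataclass
class DemographicScenario:
    """Event-list demographic model plus the SMM mutation rate.

    ``populations`` maps name -> diploid effective size at sampling time.
    ``migration`` maps (source, dest) -> per-lineage backward migration
    rate per generation (a lineage in ``source`` jumps to ``dest``).
    ``mutation_rate`` is per locus per generation.
    """

    name: str
    populations: dict[str, float]
    events: list = field(default_factory=list)
    mutation_rate: float = 3.5e-4
    migration: dict[tuple[str, str], float] = field(default_factory=dict)
    ancestral_allele: int = 200

    def sorted_events(self) -> list:
        return sorted(self.events, key=lambda e: e.time)

    def validate(self) -> None:
        """Check event consistency: every population reaches one ancestor."""
        alive = set(self.populations)
        for ev in self.sorted_events():
            if ev.time < 0:
                raise ScenarioValidationError(f"negative event time in {ev}")
            if isinstance(ev, SizeChange):
                if ev.population not in alive:
                    raise ScenarioValidationError(
                        f"size change on inactive population {ev.population!r}"
                    )
                if ev.size <= 0:
                    raise ScenarioValidationError("population size must be positive")
            elif isinstance(ev, Merge):
                if ev.child not in alive or ev.parent not in alive:
                    raise ScenarioValidationError(
                        f"merge {ev.child!r}->{ev.parent!r} with inactive population"
                    )
                alive.remove(ev.child)
            elif isinstance(ev, Admix):
                if not (0.0 <= ev.prop_a <= 1.0):
                    raise ScenarioValidationError("admixture proportion must be in [0, 1]")
                if ev.child not in alive or ev.parent_a not in alive or ev.parent_b not in alive:
                    raise ScenarioValidationError(
                        f"admixture of {ev.child!r} with inactive parent"
                    )
                alive.remove(ev.child)
            else:
                raise ScenarioValidationError(f"unknown event {ev!r}")
        for src, dst in self.migration:
            if src not in self.populations or dst not in self.populations:
                raise ScenarioValidationError(f"migration between unknown pops {src}, {dst}")
        if len(alive) != 1 and not self.migration:
            raise ScenarioValidationError(
                f"populations {sorted(alive)} never reach a common ancestor"
            )

    # -- declarative round-trip -------------------------------------------
    def to_dict(self) -> dict:
        evs = []
        for ev in self.events:
            if isinstance(ev, SizeChange):
                evs.append({"kind": "size_change", "population": ev.population,
                            "time": ev.time, "size": ev.size})
            elif isinstance(ev, Merge):
                evs.append({"kind": "merge", "child": ev.child,
                            "parent": ev.parent, "time": ev.time})
            else:
                evs.append({"kind": "admix", "child": ev.child,
                            "parent_a": ev.parent_a, "parent_b": ev.parent_b,
                            "time": ev.time, "prop_a": ev.prop_a})
        return {
            "name": self.name,
            "populations": dict(self.populations),
            "events": evs,
            "mutation_rate": self.mutation_rate,
            "migration": {f"{a}->{b}": m for (a, b), m in self.migration.items()},
            "ancestral_allele": self.ancestral_allele,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicScenario":
        events = []
        for ev in d.get("events", []):
            kind = ev["kind"]
            if kind == "size_change":
                events.append(SizeChange(ev["population"], ev["time"], ev["size"]))
            elif kind == "merge":
                events.append(Merge(ev["child"], ev["parent"], ev["time"]))
            elif kind == "admix":
                events.append(Admix(ev["child"], ev["parent_a"], ev["parent_b"],
                                    ev["time"], ev["prop_a"]))
            else:
                raise ValueError(f"unknown event kind {kind!r}")
        migration = {}
        for key, m in d.get("migration", {}).items():
            a, b = key.split("->")
            migration[(a, b)] = m
        return cls(
            name=d["name"],
            populations=dict(d["populations"]),
            events=events,
            mutation_rate=d.get("mutation_rate", 3.5e-4),
            migration=migration,
            ancestral_allele=d.get("ancestral_allele", 200),
        )


# ---------------------------------------------------------------------------
# Genealogy simulation
# ---------------------------------------------------------------------------


def simulate_genealogy(
    scn: DemographicScenario, samples: dict[str, int], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one coalescent genealogy for the given gene-copy samples.

    ``samples`` maps population name -> number of sampled gene copies.
    Returns ``(parent, node_time)`` over ``2n - 1`` nodes: tips are
    ``0..n-1`` in the order populations are listed in ``samples``, internal
    nodes follow in coalescence order, and the root's parent is ``-1``.
    Branch lengths are in generations.
    """
    scn.validate()
    n = sum(samples.values())
    if n < 2:
        raise ValueError("need at least 2 sampled gene copies")
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    node_time = np.zeros(2 * n - 1)
    sizes = dict(scn.populations)
    lineages: dict[str, list[int]] = {}
    tip = 0
    for pop, k in samples.items():
        if pop not in sizes:
            raise ScenarioValidationError(f"sample from unknown population {pop!r}")
        lineages[pop] = list(range(tip, tip + k))
        tip += k
    for pop in sizes:
        lineages.setdefault(pop, [])
    next_node = n
    t = 0.0
    events = scn.sorted_events()
    ev_idx = 0
    exp = rng.exponential
    migration = dict(scn.migration)
    has_migration = bool(migration)

    def coalesce(pop: str, at: float) -> float:
        nonlocal next_node
        lin = lineages[pop]
        i = int(rng.integers(len(lin)))
        a = lin.pop(i)
        j = int(rng.integers(len(lin)))
        b = lin.pop(j)
        parent[a] = parent[b] = next_node
        node_time[next_node] = at
        lin.append(next_node)
        next_node += 1
        return at

    while next_node < 2 * n - 1:
        t_next = events[ev_idx].time if ev_idx < len(events) else math.inf
        if not has_migration:
            # independent coalescence within each population up to t_next
            for pop, lin in lineages.items():
                tt = t
                N = sizes[pop]
                while len(lin) > 1:
                    rate = len(lin) * (len(lin) - 1) / 2.0 / (2.0 * N)
                    tt += exp(1.0 / rate)
                    if tt >= t_next:
                        break
                    coalesce(pop, tt)
            t = t_next
        else:
            # full exponential race: coalescence + migration
            rates = []
            total = 0.0
            for pop, lin in lineages.items():
                k = len(lin)
                if k >= 2:
                    r = k * (k - 1) / 2.0 / (2.0 * sizes[pop])
                    rates.append(("c", pop, r))
                    total += r
            for (src, dst), m in migration.items():
                k = len(lineages.get(src, ()))
                if k and m > 0:
                    r = k * m
                    rates.append(("m", (src, dst), r))
                    total += r
            if total == 0.0:
                if t_next is math.inf:
                    raise ScenarioValidationError(
                        "lineages stranded with no coalescence or event remaining"
                    )
                t = t_next
            else:
                dt = exp(1.0 / total)
                if t + dt >= t_next:
                    t = t_next
                else:
                    t += dt
                    u = rng.random() * total
                    acc = 0.0
                    for kind, what, r in rates:
                        acc += r
                        if u <= acc:
                            if kind == "c":
                                coalesce(what, t)
                            else:
                                src, dst = what
                                lin = lineages[src]
                                i = int(rng.integers(len(lin)))
                                lineages[dst].append(lin.pop(i))
                            break
                    continue
        if next_node >= 2 * n - 1:
            break
        if ev_idx >= len(events):
            if has_migration:
                continue
            raise ScenarioValidationError(
                "lineages stranded with no coalescence or event remaining"
            )
        ev = events[ev_idx]
        ev_idx += 1
        if isinstance(ev, SizeChange):
            sizes[ev.population] = ev.size
        elif isinstance(ev, Merge):
            lineages[ev.parent].extend(lineages.pop(ev.child, []))
            lineages[ev.child] = []
            # migration involving a removed population is switched off
            if has_migration:
                migration = {k: v for k, v in migration.items() if ev.child not in k}
                has_migration = bool(migration)
        elif isinstance(ev, Admix):
            moved = lineages.pop(ev.child, [])
            for node in moved:
                if rng.random() < ev.prop_a:
                    lineages[ev.parent_a].append(node)
                else:
                    lineages[ev.parent_b].append(node)
    return parent, node_time


def drop_mutations_smm(
    parent: np.ndarray,
    node_time: np.ndarray,
    mu: float,
    ancestral_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Overlay stepwise mutations on a genealogy; return tip allele sizes.

    Each branch receives Poisson(mu * length) mutations, each a +-1 repeat
    step with probability 1/2; the tip allele is the ancestral size plus
    the net displacement along its root path.  Sizes are never clipped.
    """
    if mu < 0:
        raise ValueError("mutation rate must be non-negative")
    n_nodes = len(parent)
    n_tips = (n_nodes + 1) // 2
    sizes = np.zeros(n_nodes, dtype=np.int64)
    root = n_nodes - 1
    sizes[root] = ancestral_size
    if mu > 0:
        branch = np.zeros(n_nodes)
        has_parent = parent >= 0
        branch[has_parent] = node_time[parent[has_parent]] - node_time[has_parent]
        k = rng.poisson(mu * branch)
        net = 2 * rng.binomial(k, 0.5) - k
    else:
        net = np.zeros(n_nodes, dtype=np.int64)
    for v in range(n_nodes - 2, -1, -1):
        sizes[v] = sizes[parent[v]] + net[v]
    return sizes[:n_tips]


def locus_rng(seed: int, locus: int) -> np.random.Generator:
    """Deterministic per-locus stream: locus count changes never shift
    the randomness of earlier loci."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(locus))))


def simulate_allele_sizes(
    scn: DemographicScenario,
    samples: dict[str, int],
    n_loci: int,
    seed: int,
) -> dict[str, np.ndarray]:
    """Simulate unlinked loci; return pop -> (n_gene_copies, n_loci) sizes.

    ``samples`` maps population -> number of diploid individuals (two gene
    copies each are simulated).
    """
    if n_loci < 1:
        raise ValueError("need at least one locus")
    gene_samples = {p: 2 * k for p, k in samples.items() if k > 0}
    out = {p: np.empty((2 * k, n_loci), dtype=np.int64) for p, k in samples.items() if k > 0}
    offsets = {}
    off = 0
    for p, k in gene_samples.items():
        offsets[p] = (off, off + k)
        off += k
    for locus in range(n_loci):
        rng = locus_rng(seed, locus)
        parent, node_time = simulate_genealogy(scn, gene_samples, rng)
        tips = drop_mutations_smm(
            parent, node_time, scn.mutation_rate, scn.ancestral_allele, rng
        )
        for p, (a, b) in offsets.items():
            out[p][:, locus] = tips[a:b]
    return out


def simulate_dataset(
    scn: DemographicScenario,
    samples: dict[str, int],
    n_loci: int | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate a diploid :class:`GenotypeMatrix` under a scenario.

    ``samples`` maps population -> number of diploid individuals.  Loci
    are independent; consecutive gene copies are paired into individuals.
    """
    n_loci = 11 if n_loci is None else n_loci
    sizes = simulate_allele_sizes(scn, samples, n_loci, seed)
    individuals = []
    pops = []
    blocks = []
    for p, arr in sizes.items():
        n_ind = arr.shape[0] // 2
        blocks.append(arr.reshape(n_ind, 2, n_loci).transpose(0, 2, 1))
        individuals.extend(f"{p}_{i}" for i in range(n_ind))
        pops.extend([p] * n_ind)
    calls = np.concatenate(blocks, axis=0)
    loci = [f"L{j + 1}" for j in range(n_loci)]
    return GenotypeMatrix(individuals, loci, calls, np.array(pops, dtype=object))


# ---------------------------------------------------------------------------
# Demographic scaling
# ---------------------------------------------------------------------------


@dataclass
class DemographicEstimates:
    """Mutation-scaled demographic MLEs for one population.

    ``d_g_mu`` is the mutation-scaled duration of the population-size
    change; divided by the per-generation mutation rate it gives the time,
    in generations, since the change started.
    """

    d_g_mu: float
    d_g_mu_ci: tuple[float, float] | None = None
    theta_current: float | None = None
    theta_founder: float | None = None
    theta_ancestral: float | None = None
    mu: float = 3.5e-4
    generation_time_years: float = 2.0


def scale_duration_to_generations(
    d_g_mu, mu: float = 3.5e-4, ci: tuple[float, float] | None = None
):
    """Convert a mutation-scaled duration D_g*mu into generations.

    generations = D_g*mu / mu, rounded to the nearest integer; CI bounds
    are scaled identically.  Accepts a bare value or a
    :class:`DemographicEstimates`.
    """
    if isinstance(d_g_mu, DemographicEstimates):
        est = d_g_mu
        return scale_duration_to_generations(est.d_g_mu, est.mu, est.d_g_mu_ci)
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    point = int(round(d_g_mu / mu))
    if ci is None:
        return point
    return point, (int(round(ci[0] / mu)), int(round(ci[1] / mu)))


def generations_to_years(generations, generation_time_years: float = 2.0) -> int:
    """Generations times the generation time, rounded to whole years."""
    if generations < 0 or generation_time_years < 0:
        raise ValueError("inputs must be non-negative")
    return int(round(generations * generation_time_years))


def founder_flush_events(
    pop: str,
    source: str,
    t_intro: float,
    founder_size: float,
    bottleneck_duration: float,
) -> list:
    """Events for a founder-flush introduction of ``pop`` from ``source``.

    Forward in time: at ``t_intro`` a founder group of ``founder_size``
    splits from ``source``, stays small for ``bottleneck_duration``
    generations, then expands to the population's present size.  Backward
    in time this is a size drop shortly before the merge.
    """
    start = max(t_intro - bottleneck_duration, 0.0)
    return [
        SizeChange(pop, start, founder_size),
        Merge(pop, source, t_intro),
    ]
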