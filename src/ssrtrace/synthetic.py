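"""Study-shaped synthetic SSR datasets with known ground truth.

The generator emulates the sampling design of the guava invasion survey:
376 diploid individuals at 11 SSR loci across five populations —
Mainland (96, subdivided into 9 latitudinal x physiographic regions),
Isabela (95), Santa Cruz (80), San Cristobal (94) and Floreana (11) —
produced by a staged island colonization with founder bottlenecks layered
on a structured mainland.  Mainland structure is a five-deme 1-D
stepping-stone along the north-south axis (nearest-neighbour migration),
which reproduces the isolation-by-distance signal without geographic
modeling.  Null alleles are overlaid post-simulation by masking gene
copies (apparent homozygotes; blank null homozygotes), keeping the
coalescent engine null-agnostic, plus a small random missingness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ssrtrace.coalescent import (
    DemographicScenario,
    Merge,
    SizeChange,
    simulate_allele_sizes,
)
from ssrtrace.genotype_io import MISSING, GenotypeMatrix

MUTATION_RATE = 3.5e-4

#: Mainland regions, their sample sizes, stepping-stone deme, and
#: synthetic centroid coordinates (lat, lon).  Deme index runs north (0)
#: to south (4); lon tracks the Coast / Highlands / Amazon axis.
MAINLAND_REGIONS: dict[str, tuple[int, int, float, float]] = {
    "NC": (8, 0, 0.6, -80.0),
    "NH": (13, 0, 0.2, -78.6),
    "NA": (12, 1, -0.2, -77.2),
    "CC": (11, 2, -1.5, -80.2),
    "CH": (11, 2, -1.9, -78.6),
    "CA": (8, 2, -2.2, -77.4),
    "SC": (10, 3, -3.3, -80.0),
    "SH": (13, 4, -4.0, -79.2),
    "SA": (10, 4, -4.3, -78.3),
}

ISLAND_COORDS = {
    "ISA": (-0.95, -91.05),
    "SCZ": (-0.62, -90.35),
    "SCY": (-0.90, -89.50),
    "FLO": (-1.30, -90.43),
}

ISLAND_SAMPLES = {"ISA": 95, "SCZ": 80, "SCY": 94, "FLO": 11}

#: Default demography: sizes anchored on the reported diversity ordering
#: (mainland He ~0.77-0.79 at SMM equilibrium; island He eroded by drift
#: since staged introductions at t4 > t3 > t2 > t1 generations ago).
DEFAULT_DEMOGRAPHY = {
    "n_mainland_deme": 8000.0,
    "migration_rate": 3e-4,  # per lineage per generation, nearest neighbours
    "t_deme_merge": 8000.0,
    "n_scy": 1000.0,
    "n_flo": 150.0,
    "n_isa": 1000.0,
    "n_scz": 5000.0,
    "n_found_scy": 5.0,
    "n_found_flo": 30.0,
    "n_found_isa": 100.0,
    "n_found_scz": 10.0,
    "t4": 1710.0,  # Mainland -> SCY
    "t3": 211.0,  # SCY -> FLO
    "t2": 119.0,  # FLO -> ISA
    "t1": 34.0,  # SCY -> SCZ
    "bottleneck_duration": 20.0,
}


@dataclass
class SyntheticTruth:
    """Ground truth stored with every generated dataset."""

    seed: int
    demography: dict
    null_beta: dict  # locus -> per-population true null frequency
    missing_rate: float
    region_deme: dict  # mainland region -> stepping-stone deme index

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        return cls(**json.loads(text))


def study_scenario(demography: dict | None = None) -> DemographicScenario:
    """The staged colonization demography over 5 mainland demes + 4 islands."""
    d = dict(DEFAULT_DEMOGRAPHY, **(demography or {}))
    pops = {f"D{i}": d["n_mainland_deme"] for i in range(5)}
    pops.update(
        SCY=d["n_scy"], FLO=d["n_flo"], ISA=d["n_isa"], SCZ=d["n_scz"]
    )
    bott = d["bottleneck_duration"]

    def intro(pop, source, t, nf):
        return [SizeChange(pop, max(t - bott, 0.0), nf), Merge(pop, source, t)]

    events = (
        intro("SCZ", "SCY", d["t1"], d["n_found_scz"])
        + intro("ISA", "FLO", d["t2"], d["n_found_isa"])
        + intro("FLO", "SCY", d["t3"], d["n_found_flo"])
        + intro("SCY", "D2", d["t4"], d["n_found_scy"])  # central deme seeds SCY
        + [
            Merge("D0", "D1", d["t_deme_merge"]),
            Merge("D4", "D3", d["t_deme_merge"] + 1),
            Merge("D1", "D2", d["t_deme_merge"] + 2),
            Merge("D3", "D2", d["t_deme_merge"] + 3),
        ]
    )
    migration = {}
    for i in range(4):
        migration[(f"D{i}", f"D{i + 1}")] = d["migration_rate"]
        migration[(f"D{i + 1}", f"D{i}")] = d["migration_rate"]
    return DemographicScenario(
        name="study-like",
        populations=pops,
        events=events,
        mutation_rate=MUTATION_RATE,
        migration=migration,
    )


def overlay_null_alleles(
    calls: np.ndarray, beta_per_locus: np.ndarray, missing_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Mask gene copies carrying a null allele, plus random missingness.

    Each gene copy is independently null with its locus's probability: a
    heterozygote with one null copy types as an apparent homozygote for
    the amplifying allele; a null homozygote types as a blank.
    """
    out = calls.copy()
    n, L, _ = out.shape
    is_null = rng.random((n, L, 2)) < beta_per_locus[None, :, None]
    both = is_null.all(axis=2)
    one = is_null[:, :, 0] & ~is_null[:, :, 1]
    other = is_null[:, :, 1] & ~is_null[:, :, 0]
    # apparent homozygote: duplicate the visible copy
    i, j = np.nonzero(one)
    out[i, j, 0] = out[i, j, 1]
    i, j = np.nonzero(other)
    out[i, j, 1] = out[i, j, 0]
    blank = both | (rng.random((n, L)) < missing_rate)
    out[blank] = MISSING
    return out


def generate_study_like(
    seed: int,
    n_loci: int = 11,
    demography: dict | None = None,
    null_beta_high: float = 0.33,
    missing_rate: float = 0.02,
) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Generate one study-shaped dataset and its ground-truth record."""
    scn = study_scenario(demography)
    samples = {f"D{i}": 0 for i in range(5)}
    for region, (n, deme, _, _) in MAINLAND_REGIONS.items():
        samples[f"D{deme}"] += n
    samples.update(ISLAND_SAMPLES)
    sizes = simulate_allele_sizes(scn, samples, n_loci, seed)

    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 987654321)))
    individuals: list[str] = []
    pops: list[str] = []
    regions: list = []
    coords: list[tuple[float, float]] = []
    blocks: list[np.ndarray] = []
    # mainland: carve each deme's individuals into its regions
    deme_cursor = {f"D{i}": 0 for i in range(5)}
    for region, (n, deme, lat, lon) in MAINLAND_REGIONS.items():
        arr = sizes[f"D{deme}"]
        start = deme_cursor[f"D{deme}"]
        block = arr[2 * start : 2 * (start + n)].reshape(n, 2, n_loci).transpose(0, 2, 1)
        deme_cursor[f"D{deme}"] += n
        blocks.append(block)
        for i in range(n):
            individuals.append(f"ML_{region}_{i}")
            pops.append("Mainland")
            regions.append(region)
            coords.append(
                (lat + rng.normal(0, 0.08), lon + rng.normal(0, 0.08))
            )
    for island, n in ISLAND_SAMPLES.items():
        arr = sizes[island]
        blocks.append(arr.reshape(n, 2, n_loci).transpose(0, 2, 1))
        lat, lon = ISLAND_COORDS[island]
        for i in range(n):
            individuals.append(f"{island}_{i}")
            pops.append(island)
            regions.append(None)
            coords.append((lat + rng.normal(0, 0.05), lon + rng.normal(0, 0.05)))
    calls = np.concatenate(blocks, axis=0)
    beta = rng.uniform(0.0, null_beta_high, size=n_loci)
    calls = overlay_null_alleles(calls, beta, missing_rate, rng)
    g = GenotypeMatrix(
        individuals,
        [f"L{j + 1}" for j in range(n_loci)],
        calls,
        np.array(pops, dtype=object),
        region=np.array(regions, dtype=object),
        coords=np.array(coords),
    )
    pop_names = ["Mainland", *ISLAND_SAMPLES]
    truth = SyntheticTruth(
        seed=int(seed),
        demography=dict(DEFAULT_DEMOGRAPHY, **(demography or {})),
        null_beta={
            f"L{j + 1}": {p: float(beta[j]) for p in pop_names} for j in range(n_loci)
        },
        missing_rate=missing_rate,
        region_deme={r: v[1] for r, v in MAINLAND_REGIONS.items()},
    )
    return g, truth


def mask_heritable_null(
    calls: np.ndarray, target_beta: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Designate one real allele per locus as a null and mask its carriers.

    Unlike :func:`overlay_null_alleles`, the null here is a heritable
    allele class (the allele whose overall frequency is closest to
    ``target_beta``), so its frequency differs between populations through
    shared ancestry — the regime where uncorrected F_ST is biased and the
    ENA correction earns its keep.  Returns the masked calls and the
    per-locus true null frequency.
    """
    out = calls.copy()
    n, L, _ = out.shape
    betas = np.zeros(L)
    for j in range(L):
        col = calls[:, j, :]
        obs = col[col[:, 0] != MISSING]
        vals, cnts = np.unique(obs, return_counts=True)
        freqs = cnts / cnts.sum()
        null_allele = vals[np.argmin(np.abs(freqs - target_beta))]
        betas[j] = freqs[np.argmin(np.abs(freqs - target_beta))]
        isnull = col == null_allele
        one = isnull[:, 0] & ~isnull[:, 1]
        other = isnull[:, 1] & ~isnull[:, 0]
        both = isnull.all(axis=1)
        out[one, j, 0] = out[one, j, 1]
        out[other, j, 1] = out[other, j, 0]
        out[both, j, :] = MISSING
    return out, betas


def generate_null_allele_benchmark(
    beta_grid, n: int, seed: int, n_alleles: int = 5
) -> list[tuple[GenotypeMatrix, float]]:
    """Single-population HWE datasets with known null frequency.

    For each beta in the grid, ``n`` diploid genotypes are drawn at one
    locus from ``n_alleles`` visible alleles (uniform frequencies scaled
    by 1 - beta) plus a null class at frequency beta, then masked the way
    a genotyping run would see them.  Returns (dataset, true beta) pairs.
    """
    datasets = []
    rng = np.random.default_rng(seed)
    for beta in beta_grid:
        if not 0 <= beta <= 0.5:
            raise ValueError("beta grid values must lie in [0, 0.5]")
        visible = np.arange(10, 10 + n_alleles)
        freqs = np.full(n_alleles, (1.0 - beta) / n_alleles)
        support = np.append(visible, -7)  # -7 marks the null allele
        p = np.append(freqs, beta)
        draws = rng.choice(support, size=(n, 2), p=p / p.sum())
        calls = np.empty((n, 1, 2), dtype=np.int64)
        for i, (a, b) in enumerate(draws):
            if a == -7 and b == -7:
                calls[i, 0] = (MISSING, MISSING)
            elif a == -7:
                calls[i, 0] = (b, b)
            elif b == -7:
                calls[i, 0] = (a, a)
            else:
                calls[i, 0] = (a, b)
        g = GenotypeMatrix(
            [f"ind{i}" for i in range(n)],
            ["L1"],
            calls,
            np.array(["pop1"] * n, dtype=object),
        )
        datasets.append((g, float(beta)))
    return datasets
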