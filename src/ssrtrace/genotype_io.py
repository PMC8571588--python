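"""Diploid SSR genotype container, file dialects, and geographic binning.

The central object is :class:`GenotypeMatrix`: individuals x loci with an
unordered pair of integer allele sizes per cell, a missing-data mask, and
population / region / coordinate metadata.  Readers and writers cover the
GenePop POP-block format and two CSV dialects (wide: two columns per locus;
long: one row per individual x locus), plus an integer-coded allele-copy
export for admixture-clustering programs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Internal sentinel for a missing allele call.  GenePop "00"/"000"
#: codes, empty CSV cells and NA all normalize to it.
MISSING: int = -1


class GenotypeParseError(ValueError):
    """Raised when a genotype file cell cannot be interpreted."""


@dataclass
class GenotypeMatrix:
    """Diploid allele-size calls per individual x locus with metadata.

    Parameters
    ----------
    individuals
        Individual identifiers, one per row.
    loci
        Locus identifiers, one per column.
    calls
        Integer array of shape ``(n_individuals, n_loci, 2)``.  A missing
        call has both entries equal to :data:`MISSING`; a homozygote has
        the same positive size twice.  Allele sizes are positive integers
        on a consistent (repeat-count or fragment-length) scale per locus.
    population
        Per-individual population label.
    region
        Optional per-individual sub-label (e.g. mainland regions).
    coords
        Optional ``(n, 2)`` array of (lat, lon) decimal degrees; NaN where
        unknown.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    population: np.ndarray
    region: np.ndarray | None = None
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        self.population = np.asarray(self.population, dtype=object)
        if self.region is not None:
            self.region = np.asarray(self.region, dtype=object)
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
        self.validate()

    # -- basic protocol ----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list:
        """Population labels in order of first appearance."""
        seen: dict = {}
        for p in self.population:
            seen.setdefault(p, None)
        return list(seen)

    def validate(self) -> None:
        n, L = self.n_individuals, self.n_loci
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} individuals x {L} loci x 2"
            )
        if self.population.shape != (n,):
            raise ValueError("population labels must be one per individual")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, j = np.argwhere(half)[0]
            raise ValueError(
                f"half-missing call at individual {self.individuals[i]!r}, "
                f"locus {self.loci[j]!r}: a call is two alleles or fully missing"
            )
        observed = self.calls[self.calls != MISSING]
        if observed.size and (observed <= 0).any():
            raise ValueError("allele sizes must be positive integers")

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def subset(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in index],
            loci=list(self.loci),
            calls=self.calls[index].copy(),
            population=self.population[index].copy(),
            region=None if self.region is None else self.region[index].copy(),
            coords=None if self.coords is None else self.coords[index].copy(),
        )

    def by_population(self, label) -> "GenotypeMatrix":
        return self.subset(self.population == label)

    def group_labels(self, by: str = "population") -> np.ndarray:
        """Per-individual grouping labels; ``by`` is 'population' or 'region'.

        For by='region', mainland individuals carry their region label and
        individuals without one fall back to their population label.
        """
        if by == "population":
            return self.population
        if by == "region":
            if self.region is None:
                raise ValueError("no region labels present")
            out = self.population.copy()
            has = np.array([r is not None and r == r and r != "" for r in self.region])
            out[has] = self.region[has]
            return out
        raise ValueError(f"unknown grouping {by!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        same_calls = np.array_equal(
            np.sort(self.calls, axis=2), np.sort(other.calls, axis=2)
        )
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and same_calls
            and np.array_equal(self.population, other.population)
        )


# ---------------------------------------------------------------------------
# Latitudinal binning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LatitudinalBinning:
    """North-south banding of a mainland transect into equal bands.

    The study area is measured from the northernmost tip southwards over
    ``extent_km`` and tiled into ``n_bands`` half-open bands ``[a, b)``;
    crossing with the physiographic axis labels yields the region grid
    (e.g. 3 bands x {Coast, Highlands, Amazon} = 9 regions).
    """

    origin_km: float = 0.0
    extent_km: float = 720.0
    n_bands: int = 3
    band_labels: tuple[str, ...] = ("North", "Central", "South")
    axis_labels: tuple[str, ...] = ("Coast", "Highlands", "Amazon")

    @property
    def band_height_km(self) -> float:
        return self.extent_km / self.n_bands

    def band_of(self, distance_from_north_km: float) -> str:
        if not (self.origin_km <= distance_from_north_km <= self.origin_km + self.extent_km):
            raise ValueError(
                f"distance {distance_from_north_km} km outside "
                f"[{self.origin_km}, {self.origin_km + self.extent_km}]"
            )
        idx = int((distance_from_north_km - self.origin_km) // self.band_height_km)
        # the exact southern endpoint belongs to the last band
        idx = min(idx, self.n_bands - 1)
        return self.band_labels[idx]


def assign_latitudinal_region(
    distance_from_north_km: float,
    axis_label: str,
    binning: LatitudinalBinning | None = None,
) -> str:
    """Map a distance-from-north and physiographic axis to a region label.

    Bands are half-open ``[a, b)``: a sample at exactly 240 km falls in the
    Central band, at 480 km in the South band.  Returns e.g.
    ``"North Coast"``.
    """
    binning = binning or LatitudinalBinning()
    if axis_label not in binning.axis_labels:
        raise ValueError(f"unknown axis label {axis_label!r}")
    return f"{binning.band_of(distance_from_north_km)} {axis_label}"


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


@dataclass
class AlleleFrequencyTable:
    """Per locus x group allele-size -> frequency maps with gene counts.

    ``freqs[(locus, group)]`` maps allele size to relative frequency among
    the observed gene copies; ``gene_counts[(locus, group)]`` is twice the
    number of non-missing individuals.  Cells with zero observed copies are
    absent from both maps rather than zero-filled.  A virtual null allele
    (see :mod:`ssrtrace.null_alleles`) is stored under the key
    :data:`NULL_ALLELE` when present.
    """

    loci: list[str]
    groups: list
    freqs: dict = field(default_factory=dict)
    gene_counts: dict = field(default_factory=dict)

    def frequencies(self, locus, group) -> dict[int, float]:
        return self.freqs[(locus, group)]

    def vector(self, locus, group, support: Iterable[int]) -> np.ndarray:
        """Frequency vector over an explicit allele support (absent = 0)."""
        f = self.freqs.get((locus, group), {})
        return np.array([f.get(a, 0.0) for a in support], dtype=float)

    def support(self, locus, groups=None) -> list[int]:
        """Sorted union of alleles observed at a locus over the groups."""
        groups = self.groups if groups is None else groups
        alleles: set[int] = set()
        for g in groups:
            alleles.update(self.freqs.get((locus, g), {}))
        return sorted(a for a in alleles if isinstance(a, (int, np.integer)))


#: Key used for the virtual null allele in corrected frequency maps.
NULL_ALLELE = "null"


def allele_frequencies(g: GenotypeMatrix, by: str = "population") -> AlleleFrequencyTable:
    """Tally observed allele frequencies per locus x group.

    Frequencies sum to 1 over the observed alleles of each non-empty cell;
    a group with zero non-missing calls at a locus is simply absent from
    the table (gene count 0), never zero-filled.
    """
    labels = g.group_labels(by)
    groups = list(dict.fromkeys(labels))
    table = AlleleFrequencyTable(loci=list(g.loci), groups=groups)
    for grp in groups:
        rows = np.flatnonzero(labels == grp)
        for j, locus in enumerate(g.loci):
            cell = g.calls[rows, j, :]
            obs = cell[cell != MISSING]
            if obs.size == 0:
                continue
            sizes, counts = np.unique(obs, return_counts=True)
            total = counts.sum()
            table.freqs[(locus, grp)] = {
                int(s): c / total for s, c in zip(sizes, counts)
            }
            table.gene_counts[(locus, grp)] = int(total)
    return table


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_DIALECTS = ("genepop", "csv-wide", "csv-long")


def read_genotypes(path, dialect: str = "genepop", missing_code: str | None = None) -> GenotypeMatrix:
    """Read a genotype file in one of the supported dialects.

    ``dialect`` is one of ``genepop`` (POP-block, 2- or 3-digit codes
    auto-detected), ``csv-wide`` (columns ``id, pop[, region, lat, lon]``
    then two columns per locus named ``<locus>.1``/``<locus>.2``) or
    ``csv-long`` (columns ``id, pop, locus, a1, a2``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "genepop":
        return _read_genepop(path)
    if dialect == "csv-wide":
        return _read_csv_wide(path, missing_code)
    if dialect == "csv-long":
        return _read_csv_long(path, missing_code)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")


def write_genotypes(g: GenotypeMatrix, path, dialect: str = "genepop") -> None:
    path = Path(path)
    if dialect == "genepop":
        _write_genepop(g, path)
    elif dialect == "csv-wide":
        _write_csv_wide(g, path)
    elif dialect == "csv-long":
        _write_csv_long(g, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")


def _read_genepop(path: Path) -> GenotypeMatrix:
    lines = path.read_text().splitlines()
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")
    # line 0 is a free title; locus names follow, either one per line or
    # comma-separated, until the first POP line
    i = 1
    loci: list[str] = []
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = [s.strip() for s in lines[i].split(",") if s.strip()]
        loci.extend(chunk)
        i += 1
    if not loci:
        raise GenotypeParseError(f"{path}: no locus names before first POP")
    individuals: list[str] = []
    pops: list[str] = []
    raw_calls: list[list[str]] = []
    pop_idx = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if line.lower() == "pop":
            pop_idx += 1
            continue
        if "," not in line:
            raise GenotypeParseError(f"{path}: line {i}: expected 'name , genotypes'")
        name, rest = line.split(",", 1)
        fields = rest.split()
        if len(fields) != len(loci):
            raise GenotypeParseError(
                f"{path}: individual {name.strip()!r}: {len(fields)} genotype "
                f"fields for {len(loci)} loci"
            )
        individuals.append(name.strip())
        pops.append(f"pop{pop_idx}")
        raw_calls.append(fields)
    if not individuals:
        raise GenotypeParseError(f"{path}: no individuals")
    # auto-detect 2- vs 3-digit encoding from field widths
    widths = {len(f) for row in raw_calls for f in row}
    if widths <= {4}:
        digits = 2
    elif widths <= {6}:
        digits = 3
    else:
        raise GenotypeParseError(
            f"{path}: inconsistent genotype field widths {sorted(widths)}; "
            "expected all 4 (2-digit) or all 6 (3-digit)"
        )
    n, L = len(individuals), len(loci)
    calls = np.full((n, L, 2), MISSING, dtype=np.int64)
    for r, row in enumerate(raw_calls):
        for c, fieldstr in enumerate(row):
            if not fieldstr.isdigit():
                raise GenotypeParseError(
                    f"{path}: individual {individuals[r]!r}, locus {loci[c]!r}: "
                    f"non-numeric genotype {fieldstr!r}"
                )
            a1 = int(fieldstr[:digits])
            a2 = int(fieldstr[digits:])
            if a1 == 0 or a2 == 0:
                continue  # missing
            calls[r, c, 0] = a1
            calls[r, c, 1] = a2
    return GenotypeMatrix(individuals, loci, calls, np.array(pops, dtype=object))


def _write_genepop(g: GenotypeMatrix, path: Path) -> None:
    max_allele = int(g.calls.max(initial=0))
    if max_allele > 999:
        raise ValueError("GenePop encoding supports allele sizes up to 999")
    digits = 3 if max_allele > 99 else 2
    out = ["ssrtrace export"]
    out.extend(g.loci)
    for pop in g.populations:
        out.append("POP")
        for i in np.flatnonzero(g.population == pop):
            fields = []
            for j in range(g.n_loci):
                a1, a2 = g.calls[i, j]
                if a1 == MISSING:
                    a1 = a2 = 0
                fields.append(f"{a1:0{digits}d}{a2:0{digits}d}")
            out.append(f"{g.individuals[i]} , " + " ".join(fields))
    path.write_text("\n".join(out) + "\n")


_MISSING_STRINGS = {"", "na", "nan", "none", "missing"}


def _parse_allele(value, where: str, missing_code: str | None) -> int:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return MISSING
    s = str(value).strip()
    if s.lower() in _MISSING_STRINGS or (missing_code is not None and s == missing_code):
        return MISSING
    try:
        a = int(float(s))
    except ValueError:
        raise GenotypeParseError(f"{where}: non-numeric allele {value!r}") from None
    if a == 0:
        return MISSING
    return a


def _read_csv_wide(path: Path, missing_code: str | None) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype=str)
    meta = [c for c in ("id", "pop", "region", "lat", "lon") if c in df.columns]
    if "id" not in meta or "pop" not in meta:
        raise GenotypeParseError(f"{path}: csv-wide needs 'id' and 'pop' columns")
    locus_cols = [c for c in df.columns if c not in meta]
    loci = []
    for c in locus_cols:
        base = re.sub(r"\.[12]$", "", c)
        if base not in loci:
            loci.append(base)
    for base in loci:
        if f"{base}.1" not in df.columns or f"{base}.2" not in df.columns:
            raise GenotypeParseError(
                f"{path}: locus {base!r} needs paired columns {base}.1 and {base}.2"
            )
    n = len(df)
    calls = np.full((n, len(loci), 2), MISSING, dtype=np.int64)
    for j, base in enumerate(loci):
        for i in range(n):
            where = f"{path}: row {i + 2}, locus {base}"
            a1 = _parse_allele(df[f"{base}.1"].iat[i], where, missing_code)
            a2 = _parse_allele(df[f"{base}.2"].iat[i], where, missing_code)
            if (a1 == MISSING) != (a2 == MISSING):
                raise GenotypeParseError(f"{where}: half-missing genotype")
            calls[i, j] = (a1, a2)
    region = df["region"].to_numpy(dtype=object) if "region" in df.columns else None
    coords = None
    if "lat" in df.columns and "lon" in df.columns:
        coords = df[["lat", "lon"]].astype(float).to_numpy()
    return GenotypeMatrix(
        list(df["id"].astype(str)),
        loci,
        calls,
        df["pop"].to_numpy(dtype=object),
        region=region,
        coords=coords,
    )


def _write_csv_wide(g: GenotypeMatrix, path: Path) -> None:
    data: dict = {"id": g.individuals, "pop": g.population}
    if g.region is not None:
        data["region"] = g.region
    if g.coords is not None:
        data["lat"] = g.coords[:, 0]
        data["lon"] = g.coords[:, 1]
    for j, locus in enumerate(g.loci):
        for k in (0, 1):
            col = g.calls[:, j, k].astype(object)
            col[col == MISSING] = ""
            data[f"{locus}.{k + 1}"] = col
    pd.DataFrame(data).to_csv(path, index=False)


def _read_csv_long(path: Path, missing_code: str | None) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype=str)
    needed = {"id", "pop", "locus", "a1", "a2"}
    if not needed <= set(df.columns):
        raise GenotypeParseError(f"{path}: csv-long needs columns {sorted(needed)}")
    individuals = list(dict.fromkeys(df["id"]))
    loci = list(dict.fromkeys(df["locus"]))
    ind_idx = {v: i for i, v in enumerate(individuals)}
    loc_idx = {v: j for j, v in enumerate(loci)}
    pops = np.empty(len(individuals), dtype=object)
    calls = np.full((len(individuals), len(loci), 2), MISSING, dtype=np.int64)
    for r in range(len(df)):
        i = ind_idx[df["id"].iat[r]]
        j = loc_idx[df["locus"].iat[r]]
        pops[i] = df["pop"].iat[r]
        where = f"{path}: row {r + 2}"
        a1 = _parse_allele(df["a1"].iat[r], where, missing_code)
        a2 = _parse_allele(df["a2"].iat[r], where, missing_code)
        if (a1 == MISSING) != (a2 == MISSING):
            raise GenotypeParseError(f"{where}: half-missing genotype")
        calls[i, j] = (a1, a2)
    return GenotypeMatrix([str(v) for v in individuals], loci, calls, pops)


def _write_csv_long(g: GenotypeMatrix, path: Path) -> None:
    rows = []
    for i, ind in enumerate(g.individuals):
        for j, locus in enumerate(g.loci):
            a1, a2 = g.calls[i, j]
            rows.append(
                {
                    "id": ind,
                    "pop": g.population[i],
                    "locus": locus,
                    "a1": "" if a1 == MISSING else int(a1),
                    "a2": "" if a2 == MISSING else int(a2),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def to_allele_copy_matrix(g: GenotypeMatrix) -> pd.DataFrame:
    """Integer-coded export with one row per allele copy, -9 for missing.

    The layout (two consecutive rows per individual, one column per locus)
    is the one admixture-clustering programs expect.
    """
    rows = []
    for i, ind in enumerate(g.individuals):
        for k in (0, 1):
            row: dict = {"id": ind, "pop": g.population[i]}
            for j, locus in enumerate(g.loci):
                a = int(g.calls[i, j, k])
                row[locus] = -9 if a == MISSING else a
            rows.append(row)
    return pd.DataFrame(rows)
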