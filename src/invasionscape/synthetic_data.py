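"""Synthetic invasions with known ground truth.

Two generators drive every downstream test:

* :func:`simulate_invasion` — spatial spread of occupied ponds from one or
  more point sources with staggered introduction years, half-normal (bivariate
  normal) dispersal with a rare long-distance tail, an optional impassable
  barrier polyline, and an imperfect per-year detection process.
* :func:`simulate_genotypes` — SNP genotypes for demes arranged along a 1-D
  river axis: two divergent founder origins (Balding–Nichols), stepping-stone
  migration with a reduced rate across one barrier, Wright–Fisher drift, and
  clutch (full-sib) family structure within sampled localities.

Both are bit-for-bit reproducible under a fixed seed. The per-locality
diversity summary of the real study system is shipped as a packaged fixture
(:func:`table1_fixture`).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .core_io import (
    GenotypeMatrix,
    Locality,
    OccurrenceRecord,
    MISSING,
    unproject_coordinates,
)

DEFAULT_REFERENCE_LONLAT = (5.0, 51.1)  # reconversion anchor for CSV export


@dataclass
class InvasionTruth:
    """Ground truth for the spatial spread process.

    sigma_true is the standard deviation (metres) of the per-year bivariate
    normal dispersal kernel; with probability ``ldd_rate`` a displacement is
    drawn from the same kernel scaled x5 (long-distance tail). The barrier is
    a polyline dispersal cannot cross. ``offspring_rate`` is the mean number
    of new ponds each occupied pond founds per year (Poisson).
    """

    sources: list[tuple[float, float, int]]
    sigma_true: float = 500.0
    detection_prob: float = 0.3
    barrier: LineString | None = None
    ldd_rate: float = 0.0
    offspring_rate: float = 0.7
    max_points: int = 3000

    def __post_init__(self) -> None:
        if not (1 <= len(self.sources) <= 10):
            raise ValueError("need 1..10 sources")
        if not (0 < self.detection_prob <= 1):
            raise ValueError("detection_prob in (0, 1]")
        if not (0 <= self.ldd_rate < 0.5):
            raise ValueError("ldd_rate in [0, 0.5)")
        if self.sigma_true < 0:
            raise ValueError("sigma_true must be >= 0")


@dataclass
class GenotypeTruth:
    """Ground truth for the genetic process.

    ``fst_between_origins`` is the Balding–Nichols target differentiation
    between the two founder allele-frequency pools. ``origin_of_deme`` assigns
    each deme (in river order) to origin 1 or 2; if None, demes up to
    ``barrier_index`` take origin 1 and the rest origin 2. Migration is
    symmetric nearest-neighbour exchange at rate ``migration_rate`` per
    generation, reduced to ``barrier_migration_rate`` across the single
    barrier between demes ``barrier_index`` and ``barrier_index + 1``.
    """

    fst_between_origins: float = 0.2
    migration_rate: float = 0.1
    barrier_migration_rate: float = 0.005
    barrier_index: int | None = None
    origin_of_deme: list[int] | None = None
    deme_size: int = 50
    clutch_size: int = 1
    missing_rate: float = 0.0
    serial_founder: bool = False
    founder_size: int = 4

    def __post_init__(self) -> None:
        for r in (self.migration_rate, self.barrier_migration_rate):
            if not (0 <= r <= 0.5):
                raise ValueError("migration rates must lie in [0, 0.5]")
        if not (0 <= self.fst_between_origins < 1):
            raise ValueError("fst_between_origins in [0, 1)")


# ---------------------------------------------------------------------------
# Spatial spread
# ---------------------------------------------------------------------------

def _crosses(barrier: LineString, x0, y0, x1, y1) -> bool:
    return barrier.intersects(LineString([(x0, y0), (x1, y1)]))


def simulate_invasion(truth: InvasionTruth, years: range, seed: int) -> list[OccurrenceRecord]:
    """Simulate occupied-pond spread and imperfect detection.

    Each year, every occupied pond founds Poisson(offspring_rate) new ponds at
    bivariate-normal displacements (x5 with probability ldd_rate);
    displacements whose segment crosses the barrier are redrawn on the same
    side. Every occupied pond is then reported as an OccurrenceRecord that
    year with probability ``detection_prob``.
    """
    years = list(years)
    if not years:
        raise ValueError("empty year range")
    if not any(y0 in years for _, _, y0 in truth.sources):
        raise ValueError("no source introduced within the simulated years")

    rng = np.random.default_rng(seed)
    occupied: list[tuple[float, float]] = []
    records: list[OccurrenceRecord] = []
    counter = 0

    for year in years:
        for sx, sy, sy0 in truth.sources:
            if sy0 == year:
                occupied.append((sx, sy))
        new_points: list[tuple[float, float]] = []
        for px, py in occupied:
            n_off = rng.poisson(truth.offspring_rate)
            for _ in range(n_off):
                for _attempt in range(50):
                    scale = truth.sigma_true * (
                        5.0 if rng.random() < truth.ldd_rate else 1.0
                    )
                    dx, dy = rng.normal(0.0, scale or 0.0, size=2) if scale > 0 else (0.0, 0.0)
                    cx, cy = px + dx, py + dy
                    if truth.barrier is None or not _crosses(truth.barrier, px, py, cx, cy):
                        new_points.append((cx, cy))
                        break
        room = truth.max_points - len(occupied)
        if room <= 0:
            new_points = []
        elif len(new_points) > room:
            idx = rng.choice(len(new_points), size=room, replace=False)
            new_points = [new_points[i] for i in sorted(idx)]
        occupied.extend(new_points)

        detected = rng.random(len(occupied)) < truth.detection_prob
        for (px, py), hit in zip(occupied, detected):
            if hit:
                records.append(OccurrenceRecord(id=f"r{counter}", x=px, y=py, year=year))
                counter += 1
    return records


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def balding_nichols_pools(
    n_loci: int, fst: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two allele-frequency pools at a target F_ST.

    Ancestral frequencies ~ Uniform(0.1, 0.9); each pool draws from
    Beta(p(1-F)/F, (1-p)(1-F)/F), whose variance p(1-p)F matches the
    Balding–Nichols differentiation model.
    """
    p = rng.uniform(0.1, 0.9, size=n_loci)
    if fst <= 0:
        return p.copy(), p.copy()
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    return rng.beta(a, b), rng.beta(a, b)


def simulate_genotypes(
    truth: GenotypeTruth,
    demes: list[Locality],
    n_loci: int,
    n_gen: int,
    samples_per_deme: int,
    seed: int,
) -> tuple[GenotypeMatrix, list[list[str]]]:
    """Wright–Fisher stepping-stone genotypes with clutch sampling.

    Demes must be ordered along the river axis. Returns the genotype matrix
    and the pedigree: a list of full-sib sets (lists of individual ids).
    """
    if n_loci < 50:
        raise ValueError("n_loci must be >= 50")
    n_demes = len(demes)
    if n_demes < 1:
        raise ValueError("need at least one deme")
    N = truth.deme_size
    if samples_per_deme > 2 * N:
        raise ValueError(f"samples_per_deme {samples_per_deme} exceeds 2N = {2 * N}")

    rng = np.random.default_rng(seed)
    pool1, pool2 = balding_nichols_pools(n_loci, truth.fst_between_origins, rng)

    barrier_index = truth.barrier_index
    origins = truth.origin_of_deme
    if origins is None:
        if barrier_index is None:
            barrier_index = n_demes // 2 - 1
        origins = [1 if d <= barrier_index else 2 for d in range(n_demes)]
    if len(origins) != n_demes:
        raise ValueError("origin_of_deme length must match demes")

    freqs = np.empty((n_demes, n_loci))
    if truth.serial_founder:
        # sequential colonisation: each deme founded from its upstream
        # neighbour through a bottleneck of founder_size diploids
        freqs[0] = pool1 if origins[0] == 1 else pool2
        for d in range(1, n_demes):
            k = 2 * truth.founder_size
            freqs[d] = rng.binomial(k, freqs[d - 1]) / k
    else:
        for d in range(n_demes):
            freqs[d] = pool1 if origins[d] == 1 else pool2

    # stepping-stone drift
    m = truth.migration_rate
    for _ in range(n_gen):
        mixed = freqs.copy()
        for d in range(n_demes):
            for nb in (d - 1, d + 1):
                if not (0 <= nb < n_demes):
                    continue
                rate = m
                if barrier_index is not None and {d, nb} == {barrier_index, barrier_index + 1}:
                    rate = truth.barrier_migration_rate
                mixed[d] += rate * (freqs[nb] - freqs[d])
        freqs = rng.binomial(2 * N, np.clip(mixed, 0.0, 1.0)) / (2 * N)

    # sampling with clutch structure
    individuals: list[str] = []
    locality_of: dict[str, int] = {}
    rows: list[np.ndarray] = []
    pedigree: list[list[str]] = []
    for d, deme in enumerate(demes):
        p = freqs[d]
        remaining = samples_per_deme
        while remaining > 0:
            c = min(max(truth.clutch_size, 1), remaining)
            if c >= 2:
                par1 = rng.binomial(2, p)
                par2 = rng.binomial(2, p)
                sib_ids = []
                for _ in range(c):
                    g = (rng.random(n_loci) < par1 / 2).astype(np.int8) + (
                        rng.random(n_loci) < par2 / 2
                    ).astype(np.int8)
                    ind = f"L{deme.locality_id}_i{samples_per_deme - remaining}"
                    individuals.append(ind)
                    locality_of[ind] = deme.locality_id
                    rows.append(g)
                    sib_ids.append(ind)
                    remaining -= 1
                pedigree.append(sib_ids)
            else:
                g = rng.binomial(2, p).astype(np.int8)
                ind = f"L{deme.locality_id}_i{samples_per_deme - remaining}"
                individuals.append(ind)
                locality_of[ind] = deme.locality_id
                rows.append(g)
                remaining -= 1

    calls = np.asarray(rows, dtype=np.int8)
    if truth.missing_rate > 0:
        mask = rng.random(calls.shape) < truth.missing_rate
        calls[mask] = MISSING

    G = GenotypeMatrix(
        individuals=individuals,
        loci=[f"snp{j}" for j in range(n_loci)],
        calls=calls,
        locality_of=locality_of,
    )
    return G, pedigree


def expected_drift_fst(N: int, t: int) -> float:
    """Expected F_ST between isolated demes after t generations of drift."""
    return 1.0 - (1.0 - 1.0 / (2 * N)) ** t


# ---------------------------------------------------------------------------
# Packaged study-system fixture
# ---------------------------------------------------------------------------

def table1_fixture(full: bool = False) -> pd.DataFrame:
    """Per-locality diversity summary of the real study system.

    Returns the 28 localities with reported statistics (three localities with
    a single sampled individual carry none and are excluded unless
    ``full=True``). Columns: locality_id, latitude, longitude, n,
    n_excl_fullsib, he, ho, fis.
    """
    with resources.files("invasionscape.data").joinpath("table1.csv").open() as fh:
        table = pd.read_csv(fh)
    if full:
        return table
    return table.dropna(subset=["ho", "he", "fis"]).reset_index(drop=True)


def table1_localities(reference: tuple[float, float] = DEFAULT_REFERENCE_LONLAT) -> list[Locality]:
    """The 31 study localities as projected :class:`Locality` objects."""
    from .core_io import project_coordinates

    table = table1_fixture(full=True)
    xy = project_coordinates(
        list(zip(table.longitude, table.latitude)), reference
    )
    return [
        Locality(locality_id=int(r.locality_id), x=x, y=y,
                 n_sampled=int(r.n) if pd.notna(r.n) else 0)
        for r, (x, y) in zip(table.itertuples(), xy)
    ]


# ---------------------------------------------------------------------------
# File export (standard formats of core_io)
# ---------------------------------------------------------------------------

def write_occurrences_csv(
    records: list[OccurrenceRecord],
    path,
    reference: tuple[float, float] = DEFAULT_REFERENCE_LONLAT,
) -> None:
    """Write records as the occurrence CSV dialect (WGS84 lon/lat)."""
    lonlat = unproject_coordinates([(r.x, r.y) for r in records], reference)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "longitude", "latitude", "year", "verified"])
        for rec, (lon, lat) in zip(records, lonlat):
            w.writerow([rec.id, f"{lon:.8f}", f"{lat:.8f}", rec.year,
                        str(rec.verified).lower()])


def write_localities_csv(
    localities: list[Locality],
    path,
    reference: tuple[float, float] = DEFAULT_REFERENCE_LONLAT,
) -> None:
    lonlat = unproject_coordinates([(l.x, l.y) for l in localities], reference)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["locality_id", "latitude", "longitude", "n_sampled"])
        for loc, (lon, lat) in zip(localities, lonlat):
            w.writerow([loc.locality_id, f"{lat:.8f}", f"{lon:.8f}", loc.n_sampled])
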