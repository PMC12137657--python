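"""Domain types, coordinate projection, and I/O for every format the pipeline touches.

All downstream spatial math runs in planar metres. Geographic input (WGS84
decimal degrees) is converted once, at read time, with a local equirectangular
projection about a reference point; over the few tens of kilometres this
pipeline targets, the distortion is far below the 1-km buffers and 200-m
thinning radii used downstream.

Formats handled here: occurrence/locality/012-genotype CSV, VCF (biallelic
SNPs), ESRI ASCII grids for every raster surface, and GeoJSON LineString
collections for river networks.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from shapely.geometry import LineString, Point
from shapely.ops import nearest_points

logger = logging.getLogger("invasionscape")

EARTH_RADIUS_M = 6_371_000.0
MISSING = -1  # sentinel for a missing genotype call


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OccurrenceRecord:
    """One dated, verified point observation in planar metres."""

    id: str
    x: float
    y: float
    year: int
    verified: bool = True

    def __post_init__(self) -> None:
        if not (1900 <= self.year <= 2100):
            raise ValueError(f"year {self.year} outside [1900, 2100]")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("coordinates must be finite")


@dataclass(frozen=True)
class Locality:
    """A sampled pond: id, planar position and number of genotyped individuals."""

    locality_id: int
    x: float
    y: float
    n_sampled: int = 0

    def __post_init__(self) -> None:
        if self.n_sampled < 0:
            raise ValueError("n_sampled must be >= 0")


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes coded as alternate-allele counts 0/1/2.

    ``calls`` is an (n_individuals, n_loci) int8 array with :data:`MISSING`
    (-1) marking missing calls. ``locality_of`` maps every individual id to a
    locality id.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    locality_of: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate locus ids")
        if len(self.individuals) < 2 or len(self.loci) < 1:
            raise ValueError("need at least 2 individuals and 1 locus")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.loci)):
            raise ValueError("calls shape does not match ids")
        missing = [i for i in self.individuals if i not in self.locality_of]
        if missing:
            raise ValueError(f"individuals absent from locality map: {missing[:5]}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locality_ids(self) -> list[int]:
        """Distinct locality ids in order of first appearance."""
        seen: dict[int, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.locality_of[ind], None)
        return list(seen)

    def subset_individuals(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.individuals.index(i) for i in keep]
        return GenotypeMatrix(
            individuals=list(keep),
            loci=list(self.loci),
            calls=self.calls[idx, :].copy(),
            locality_of={i: self.locality_of[i] for i in keep},
        )

    def by_locality(self) -> dict[int, np.ndarray]:
        """Per-locality views of the call matrix (row subsets)."""
        out: dict[int, list[int]] = {}
        for row, ind in enumerate(self.individuals):
            out.setdefault(self.locality_of[ind], []).append(row)
        return {loc: self.calls[rows, :] for loc, rows in out.items()}


@dataclass
class RasterGrid:
    """Row-major raster; origin is the lower-left corner, ``values[0]`` the top row.

    This matches the ESRI ASCII grid convention used by every surface module
    (geoprofile posterior, hit scores, resistance, diversity).
    """

    x_origin: float
    y_origin: float
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing planar point (x, y)."""
        col = int((x - self.x_origin) // self.cell_size)
        row_from_bottom = int((y - self.y_origin) // self.cell_size)
        row = self.n_rows - 1 - row_from_bottom
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"point ({x}, {y}) outside grid")
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.x_origin + (col + 0.5) * self.cell_size
        y = self.y_origin + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(self.x_origin, self.y_origin, self.cell_size,
                          np.asarray(values, dtype=float), self.nodata)

    def same_grid(self, other: "RasterGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.x_origin, other.x_origin)
            and math.isclose(self.y_origin, other.y_origin)
            and math.isclose(self.cell_size, other.cell_size)
        )


def make_grid(
    bounds: tuple[float, float, float, float],
    cell_size: float,
    nodata: float = -9999.0,
) -> RasterGrid:
    """Empty raster covering (xmin, ymin, xmax, ymax) at the given cell size."""
    xmin, ymin, xmax, ymax = bounds
    n_cols = max(int(math.ceil((xmax - xmin) / cell_size)), 1)
    n_rows = max(int(math.ceil((ymax - ymin) / cell_size)), 1)
    return RasterGrid(x_origin=xmin, y_origin=ymin, cell_size=cell_size,
                      values=np.zeros((n_rows, n_cols)), nodata=nodata)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    labels: list
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")

    def get(self, a, b) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])


# ---------------------------------------------------------------------------
# Coordinate projection
# ---------------------------------------------------------------------------

def project_coordinates(
    lonlat: list[tuple[float, float]],
    reference: tuple[float, float],
) -> list[tuple[float, float]]:
    """Project (lon, lat) degrees to planar metres about ``reference``.

    Local equirectangular: x = R cos(lat0) dlon, y = R dlat (radians),
    R = 6 371 000 m. Exact inverse: :func:`unproject_coordinates`.
    """
    lon0, lat0 = reference
    _check_lonlat([reference])
    _check_lonlat(lonlat)
    coslat0 = math.cos(math.radians(lat0))
    out = []
    for lon, lat in lonlat:
        x = EARTH_RADIUS_M * coslat0 * math.radians(lon - lon0)
        y = EARTH_RADIUS_M * math.radians(lat - lat0)
        out.append((x, y))
    return out


def unproject_coordinates(
    xy: list[tuple[float, float]],
    reference: tuple[float, float],
) -> list[tuple[float, float]]:
    """Inverse of :func:`project_coordinates`; round-trips to <1e-6 degrees."""
    lon0, lat0 = reference
    coslat0 = math.cos(math.radians(lat0))
    out = []
    for x, y in xy:
        lon = lon0 + math.degrees(x / (EARTH_RADIUS_M * coslat0))
        lat = lat0 + math.degrees(y / EARTH_RADIUS_M)
        out.append((lon, lat))
    return out


def _check_lonlat(pts) -> None:
    for lon, lat in pts:
        if not (-90.0 <= lat <= 90.0):
            raise ValueError(f"latitude {lat} outside [-90, 90]")
        if not (-360.0 <= lon <= 360.0):
            raise ValueError(f"longitude {lon} out of range")


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------

def read_occurrences(
    path,
    reference: tuple[float, float] | None = None,
) -> list[OccurrenceRecord]:
    """Read occurrence CSV (id, longitude, latitude, year, verified).

    Unverified rows are dropped (with a logged count), as are rows whose year
    does not parse. Coordinates are projected about ``reference`` (default:
    mean lon/lat of the verified rows).
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "longitude", "latitude", "year", "verified"}
        header = set(reader.fieldnames or [])
        missing = required - header
        if missing:
            raise ValueError(f"occurrence CSV missing column(s): {sorted(missing)}")
        rows = list(reader)

    kept, n_unverified, n_bad_year = [], 0, 0
    for row in rows:
        if str(row["verified"]).strip().lower() not in {"true", "1", "yes", "t"}:
            n_unverified += 1
            continue
        try:
            year = int(row["year"])
        except (TypeError, ValueError):
            n_bad_year += 1
            logger.warning("occurrence %s: unparseable year %r, row rejected",
                           row["id"], row["year"])
            continue
        kept.append((row["id"], float(row["longitude"]), float(row["latitude"]), year))

    if n_unverified:
        logger.info("dropped %d unverified occurrence rows", n_unverified)
    if n_bad_year:
        logger.info("rejected %d occurrence rows with unparseable years", n_bad_year)
    if not kept:
        return []

    lonlat = [(lon, lat) for _, lon, lat, _ in kept]
    if reference is None:
        reference = (
            sum(p[0] for p in lonlat) / len(lonlat),
            sum(p[1] for p in lonlat) / len(lonlat),
        )
    xy = project_coordinates(lonlat, reference)
    return [
        OccurrenceRecord(id=i, x=x, y=y, year=yr)
        for (i, _, _, yr), (x, y) in zip(kept, xy)
    ]


def read_localities(path, reference: tuple[float, float] | None = None) -> list[Locality]:
    """Read locality CSV (locality_id, latitude, longitude[, n_sampled])."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = set(reader.fieldnames or [])
        required = {"locality_id", "latitude", "longitude"}
        missing = required - header
        if missing:
            raise ValueError(f"locality CSV missing column(s): {sorted(missing)}")
        rows = list(reader)
    lonlat = [(float(r["longitude"]), float(r["latitude"])) for r in rows]
    if reference is None:
        reference = (
            sum(p[0] for p in lonlat) / len(lonlat),
            sum(p[1] for p in lonlat) / len(lonlat),
        )
    xy = project_coordinates(lonlat, reference)
    return [
        Locality(
            locality_id=int(r["locality_id"]),
            x=x, y=y,
            n_sampled=int(r.get("n_sampled", 0) or 0),
        )
        for r, (x, y) in zip(rows, xy)
    ]


# ---------------------------------------------------------------------------
# Genotype readers/writers
# ---------------------------------------------------------------------------

def read_genotypes(path, locality_map: dict[str, int] | str) -> GenotypeMatrix:
    """Read genotypes from a VCF (*.vcf) or a 0/1/2 matrix CSV.

    The two representations of the same cohort produce an identical
    :class:`GenotypeMatrix`. ``locality_map`` is either a dict or the path of
    a two-column CSV (individual, locality_id).
    """
    if isinstance(locality_map, (str,)) or hasattr(locality_map, "__fspath__"):
        locality_map = _read_locality_map(locality_map)
    path = str(path)
    if path.endswith(".vcf") or path.endswith(".vcf.gz"):
        individuals, loci, calls = _read_vcf(path)
    else:
        individuals, loci, calls = _read_012_csv(path)
    missing = [i for i in individuals if i not in locality_map]
    if missing:
        raise ValueError(f"individuals absent from locality map: {missing[:5]}")
    return GenotypeMatrix(individuals, loci, calls,
                          {i: locality_map[i] for i in individuals})


def _read_locality_map(path) -> dict[str, int]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = set(reader.fieldnames or [])
        if not {"individual", "locality_id"} <= header:
            raise ValueError("locality map CSV needs columns individual, locality_id")
        return {r["individual"]: int(r["locality_id"]) for r in reader}


def _read_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(path)
    individuals = list(vcf.samples)
    loci, rows, n_skipped = [], [], 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = var.genotype.array()  # (n, 3): allele1, allele2, phased
        a1, a2 = gts[:, 0], gts[:, 1]
        calls = np.where((a1 < 0) | (a2 < 0), MISSING, a1 + a2).astype(np.int8)
        rows.append(calls)
        loci.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
    if n_skipped:
        logger.warning("skipped %d non-biallelic-SNP VCF sites", n_skipped)
    return individuals, loci, np.asarray(rows, dtype=np.int8).T


def _read_012_csv(path):
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if not header or header[0] != "individual":
            raise ValueError("012 CSV must start with an 'individual' header column")
        loci = header[1:]
        individuals, rows = [], []
        for row in reader:
            individuals.append(row[0])
            vals = [MISSING if v in ("", "NA", ".", "-1") else int(v) for v in row[1:]]
            if any(v not in (0, 1, 2, MISSING) for v in vals):
                raise ValueError(f"invalid 012 call in row for {row[0]}")
            rows.append(vals)
    return individuals, loci, np.asarray(rows, dtype=np.int8)


def write_genotypes_csv(G: GenotypeMatrix, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["individual", *G.loci])
        for ind, row in zip(G.individuals, G.calls):
            w.writerow([ind, *("NA" if v == MISSING else int(v) for v in row)])


def write_genotypes_vcf(G: GenotypeMatrix, path) -> None:
    """Write a minimal plain-text biallelic VCF (A/T alleles, one fake contig)."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.individuals) + "\n")
        for j, locus in enumerate(G.loci):
            cells = "\t".join(gt_str[int(v)] for v in G.calls[:, j])
            fh.write(f"1\t{j + 1}\t{locus}\tA\tT\t.\tPASS\t.\tGT\t{cells}\n")


def write_locality_map(locality_of: dict[str, int], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["individual", "locality_id"])
        for ind, loc in locality_of.items():
            w.writerow([ind, loc])


# ---------------------------------------------------------------------------
# ESRI ASCII raster I/O
# ---------------------------------------------------------------------------

def write_raster(grid: RasterGrid, path) -> None:
    """Write an ESRI ASCII grid; :func:`read_raster` is its exact inverse."""
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_origin!r}\n")
        fh.write(f"yllcorner {grid.y_origin!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_raster(path) -> RasterGrid:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = val
        values = np.loadtxt(fh, dtype=float, ndmin=2)
    grid = RasterGrid(
        x_origin=float(header["xllcorner"]),
        y_origin=float(header["yllcorner"]),
        cell_size=float(header["cellsize"]),
        values=values,
        nodata=float(header["nodata_value"]),
    )
    if grid.values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("raster body does not match declared nrows/ncols")
    return grid


# ---------------------------------------------------------------------------
# River network distance
# ---------------------------------------------------------------------------

SNAP_TOLERANCE_M = 1.0  # endpoints closer than this are the same node


def read_geojson_lines(path) -> list[LineString]:
    """Read every LineString from a GeoJSON FeatureCollection or geometry."""
    with open(path) as fh:
        gj = json.load(fh)
    geoms = []

    def _collect(geom):
        if geom["type"] == "LineString":
            geoms.append(LineString(geom["coordinates"]))
        elif geom["type"] == "MultiLineString":
            geoms.extend(LineString(c) for c in geom["coordinates"])
        elif geom["type"] == "GeometryCollection":
            for g in geom["geometries"]:
                _collect(g)

    if gj.get("type") == "FeatureCollection":
        for feat in gj["features"]:
            _collect(feat["geometry"])
    else:
        _collect(gj)
    if not geoms:
        raise ValueError("no LineString geometries found")
    return geoms


def river_distance(localities: list[Locality], network: list[LineString]) -> DistanceMatrix:
    """Shortest along-network distance between localities snapped to the network.

    Segment endpoints within :data:`SNAP_TOLERANCE_M` are merged into one graph
    node; each locality is snapped to its nearest point on the network (the
    off-network snap distance is *not* added to path lengths). Raises if any
    two queried localities fall in disconnected components.
    """
    graph = nx.Graph()

    def node_key(x, y):
        return (round(x / SNAP_TOLERANCE_M), round(y / SNAP_TOLERANCE_M))

    # enumerate all segments
    segments = []  # (a, b) coordinate pairs
    for line in network:
        coords = list(line.coords)
        segments.extend(zip(coords[:-1], coords[1:]))

    # snap each locality to its globally nearest segment, remembering the
    # parametric position so segments can be split at the snap points
    snaps_on_segment: dict[int, list[tuple[float, str]]] = {}
    for loc in localities:
        p = Point(loc.x, loc.y)
        best_i, best_d = None, float("inf")
        for i, (a, b) in enumerate(segments):
            d = LineString([a, b]).distance(p)
            if d < best_d:
                best_i, best_d = i, d
        (x0, y0), (x1, y1) = segments[best_i]
        seg_len2 = (x1 - x0) ** 2 + (y1 - y0) ** 2
        t = 0.0 if seg_len2 == 0 else max(0.0, min(1.0, (
            (loc.x - x0) * (x1 - x0) + (loc.y - y0) * (y1 - y0)) / seg_len2))
        snaps_on_segment.setdefault(best_i, []).append((t, f"loc{loc.locality_id}"))

    # build the graph, splitting segments at snap points
    for i, ((x0, y0), (x1, y1)) in enumerate(segments):
        chain = [(0.0, node_key(x0, y0))]
        chain += sorted(snaps_on_segment.get(i, []))
        chain.append((1.0, node_key(x1, y1)))
        seg_len = math.hypot(x1 - x0, y1 - y0)
        for (ta, na), (tb, nb) in zip(chain[:-1], chain[1:]):
            graph.add_edge(na, nb, weight=(tb - ta) * seg_len)

    loc_nodes = [f"loc{loc.locality_id}" for loc in localities]
    comps = list(nx.connected_components(graph))
    comp_of = {}
    for ci, comp in enumerate(comps):
        for node in comp:
            comp_of[node] = ci
    used = {comp_of[n] for n in loc_nodes}
    if len(used) > 1:
        raise ValueError(
            f"river network is disconnected across queried localities: "
            f"{len(used)} components involved"
        )

    n = len(localities)
    d = np.zeros((n, n))
    for i in range(n):
        lengths = nx.single_source_dijkstra_path_length(graph, loc_nodes[i])
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = lengths[loc_nodes[j]]
    return DistanceMatrix(labels=[loc.locality_id for loc in localities], d=d)


def euclidean_distance(localities: list[Locality]) -> DistanceMatrix:
    """Pairwise straight-line distances between localities, in metres."""
    xy = np.array([(loc.x, loc.y) for loc in localities])
    diff = xy[:, None, :] - xy[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    return DistanceMatrix(labels=[loc.locality_id for loc in localities], d=d)
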