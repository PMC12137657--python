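"""Landscape resistance from isolation-by-distance residuals, and moving-window
diversity surfaces.

The IBD trend is fitted across individual pairs within a distance cutoff as
genetic_distance = a + b * log(1 + geographic_distance); pair residuals
(observed - fitted, rescaled to [-1, 1] by the maximum absolute residual) are
spread along the straight segment joining the pair. A grid cell's resistance
is the mean residual of the segments crossing it; significance comes from
resampling the same number of residuals from the full pool without
replacement — cells above the upper null quantile are barriers (less gene
flow than the trend predicts), below the lower quantile corridors.

The diversity surface pools individuals in a window x window block of cells
around each cell, controls sampling intensity by rarefaction (mean observed
heterozygosity over repeated draws of a fixed number of individuals), and
fills unsampled cells by ordinary kriging with an exponential variogram
(inverse-distance weighting as a logged fallback when the variogram fit
fails).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit
from shapely.geometry import LineString, box
from shapely.strtree import STRtree

from .core_io import DistanceMatrix, GenotypeMatrix, Locality, MISSING, RasterGrid

logger = logging.getLogger("invasionscape")

CLASS_CORRIDOR, CLASS_NOT_SIGNIFICANT, CLASS_BARRIER = -1, 0, 1


@dataclass
class IBDResiduals:
    pairs: list[tuple[str, str]]
    residuals: np.ndarray           # scaled to [-1, 1]
    segments: list[tuple[tuple[float, float], tuple[float, float]]]
    intercept: float
    slope: float
    d_max: float


@dataclass
class ResistanceSurface:
    grid: RasterGrid                # mean residual per crossed cell
    significance: RasterGrid        # {-1, 0, +1}, nodata where uncrossed
    d_max: float
    n_resample: int


@dataclass
class DiversitySurface:
    grid: RasterGrid
    window: int
    rarefaction_n: int


# ---------------------------------------------------------------------------
# IBD residuals
# ---------------------------------------------------------------------------

def fit_ibd_residuals(
    genetic: DistanceMatrix,
    coords: dict[str, tuple[float, float]],
    d_max: float,
) -> IBDResiduals:
    """Least-squares IBD fit over pairs within d_max, residuals scaled to [-1, 1]."""
    labels = genetic.labels
    pairs, g_list, d_list, segs = [], [], [], []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            (xa, ya), (xb, yb) = coords[a], coords[b]
            d = math.hypot(xa - xb, ya - yb)
            gd = genetic.d[i, j]
            if d <= d_max and np.isfinite(gd):
                pairs.append((a, b))
                g_list.append(gd)
                d_list.append(d)
                segs.append(((xa, ya), (xb, yb)))
    if len(pairs) < 10:
        raise ValueError(f"need >= 10 pairs within d_max; got {len(pairs)}")
    d_arr = np.asarray(d_list)
    if np.ptp(d_arr) == 0:
        raise ValueError("degenerate geometry: all pairs at the same distance")
    X = np.log1p(d_arr)
    A = np.column_stack([np.ones_like(X), X])
    (a0, b0), *_ = np.linalg.lstsq(A, np.asarray(g_list), rcond=None)
    resid = np.asarray(g_list) - (a0 + b0 * X)
    scale = np.abs(resid).max()
    if scale > 1e-12:  # a numerically perfect fit stays at zero
        resid = resid / scale
    return IBDResiduals(pairs=pairs, residuals=resid, segments=segs,
                        intercept=float(a0), slope=float(b0), d_max=d_max)


# ---------------------------------------------------------------------------
# Resistance mapping
# ---------------------------------------------------------------------------

def cells_crossed(grid: RasterGrid, segment) -> list[tuple[int, int]]:
    """Grid cells whose square intersects the segment (exact geometry)."""
    (x0, y0), (x1, y1) = segment
    line = LineString([(x0, y0), (x1, y1)])
    out = []
    cs = grid.cell_size
    cmin = max(int((min(x0, x1) - grid.x_origin) // cs), 0)
    cmax = min(int((max(x0, x1) - grid.x_origin) // cs), grid.n_cols - 1)
    rb_min = max(int((min(y0, y1) - grid.y_origin) // cs), 0)
    rb_max = min(int((max(y0, y1) - grid.y_origin) // cs), grid.n_rows - 1)
    for col in range(cmin, cmax + 1):
        for rb in range(rb_min, rb_max + 1):
            cell = box(grid.x_origin + col * cs, grid.y_origin + rb * cs,
                       grid.x_origin + (col + 1) * cs, grid.y_origin + (rb + 1) * cs)
            if cell.intersects(line):
                out.append((grid.n_rows - 1 - rb, col))
    return out


def map_resistance(
    residuals: IBDResiduals,
    grid: RasterGrid,
    n_resample: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> ResistanceSurface:
    """Mean IBD residual per crossed cell with resampling significance classes.

    Null per cell: ``n_resample`` draws of the cell's segment count from the
    full residual pool without replacement; two-sided test at ``alpha``
    (alpha/2 per tail). Cells crossed by no segment are nodata.
    """
    pool = np.sort(residuals.residuals)  # sorted: order-independent nulls
    n_pool = len(pool)
    cell_resid: dict[tuple[int, int], list[float]] = {}
    for seg, r in zip(residuals.segments, residuals.residuals):
        for cell in cells_crossed(grid, seg):
            cell_resid.setdefault(cell, []).append(float(r))

    mean_grid = np.full(grid.values.shape, grid.nodata)
    sig_grid = np.full(grid.values.shape, grid.nodata)
    null_cache: dict[int, tuple[float, float]] = {}
    for (row, col), vals in sorted(cell_resid.items()):
        # summing in sorted order makes the cell mean independent of the
        # order residual labels arrived in
        obs = float(np.mean(np.sort(vals)))
        mean_grid[row, col] = obs
        n_c = len(vals)
        if n_c not in null_cache:
            if n_c >= n_pool:
                null_cache[n_c] = (-np.inf, np.inf)  # degenerate: full pool
            else:
                # the null depends only on the draw size, so key its RNG on
                # (seed, n_c): classifications are then invariant to pair
                # relabelling
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=seed, spawn_key=(n_c,)))
                draws = np.empty(n_resample)
                for t in range(n_resample):
                    draws[t] = pool[rng.choice(n_pool, size=n_c,
                                               replace=False)].mean()
                null_cache[n_c] = (
                    float(np.quantile(draws, alpha / 2)),
                    float(np.quantile(draws, 1 - alpha / 2)),
                )
        lo, hi = null_cache[n_c]
        if obs > hi:
            sig_grid[row, col] = CLASS_BARRIER
        elif obs < lo:
            sig_grid[row, col] = CLASS_CORRIDOR
        else:
            sig_grid[row, col] = CLASS_NOT_SIGNIFICANT

    return ResistanceSurface(
        grid=grid.copy_with(mean_grid),
        significance=grid.copy_with(sig_grid),
        d_max=residuals.d_max,
        n_resample=n_resample,
    )


# ---------------------------------------------------------------------------
# Moving-window diversity
# ---------------------------------------------------------------------------

def windowed_heterozygosity(
    G: GenotypeMatrix,
    coords: dict[str, tuple[float, float]],
    grid: RasterGrid,
    window: int = 10,
    rarefaction_n: int = 5,
    n_draws: int = 100,
    seed: int = 0,
) -> DiversitySurface:
    """Rarefied observed heterozygosity per cell from a window x window block.

    A cell gets a value only if at least ``rarefaction_n`` individuals fall in
    the surrounding block; the estimate is the mean, over ``n_draws`` seeded
    draws of ``rarefaction_n`` individuals, of the drawn set's mean per-locus
    heterozygosity. A block holding exactly ``rarefaction_n`` individuals
    reduces to their direct Ho.
    """
    if rarefaction_n < 2:
        raise ValueError("rarefaction_n must be >= 2")
    rng = np.random.default_rng(seed)
    # locate individuals on the grid
    rowcol: list[tuple[int, int] | None] = []
    for ind in G.individuals:
        x, y = coords[ind]
        try:
            rowcol.append(grid.cell_of(x, y))
        except IndexError:
            rowcol.append(None)

    half = window // 2
    vals = np.full(grid.values.shape, grid.nodata)
    calls = G.calls
    het = calls == 1
    obs = calls != MISSING
    for row in range(grid.n_rows):
        for col in range(grid.n_cols):
            members = [
                i for i, rc in enumerate(rowcol)
                if rc is not None
                and abs(rc[0] - row) <= half and abs(rc[1] - col) <= half
            ]
            if len(members) < rarefaction_n:
                continue
            members = np.asarray(members)
            if len(members) == rarefaction_n:
                vals[row, col] = _subset_ho(het, obs, members)
            else:
                acc = 0.0
                for _ in range(n_draws):
                    sub = rng.choice(members, size=rarefaction_n, replace=False)
                    acc += _subset_ho(het, obs, sub)
                vals[row, col] = acc / n_draws
    return DiversitySurface(grid=grid.copy_with(vals), window=window,
                            rarefaction_n=rarefaction_n)


def _subset_ho(het: np.ndarray, obs: np.ndarray, rows: np.ndarray) -> float:
    """Mean per-locus observed heterozygosity of a subset of individuals."""
    n = obs[rows].sum(axis=0)
    h = het[rows].sum(axis=0)
    use = n > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        return float((h[use] / n[use]).mean())


# ---------------------------------------------------------------------------
# Kriging
# ---------------------------------------------------------------------------

def krige_surface(partial: DiversitySurface) -> DiversitySurface:
    """Fill undefined cells by ordinary kriging (exponential variogram, nugget 0).

    Defined cells are retained exactly. Falls back to inverse-distance
    weighting, with a logged flag, when the variogram cannot be fitted.
    """
    grid = partial.grid
    defined = grid.values != grid.nodata
    if defined.sum() < 5:
        raise ValueError("need >= 5 defined cells")
    known_rc = np.argwhere(defined)
    known_xy = np.array([grid.cell_center(r, c) for r, c in known_rc])
    known_v = grid.values[defined]
    target_rc = np.argwhere(~defined)
    if len(target_rc) == 0:
        return DiversitySurface(grid.copy_with(grid.values.copy()),
                                partial.window, partial.rarefaction_n)
    target_xy = np.array([grid.cell_center(r, c) for r, c in target_rc])

    filled = grid.values.copy()
    try:
        preds = _ordinary_krige(known_xy, known_v, target_xy)
    except Exception as exc:  # singular system or failed variogram fit
        logger.warning("kriging failed (%s); falling back to inverse-distance "
                       "weighting", exc)
        preds = _idw(known_xy, known_v, target_xy)
    for (r, c), v in zip(target_rc, preds):
        filled[r, c] = v
    return DiversitySurface(grid.copy_with(filled), partial.window,
                            partial.rarefaction_n)


def _ordinary_krige(known_xy, known_v, target_xy):
    d_known = np.sqrt(((known_xy[:, None] - known_xy[None]) ** 2).sum(axis=2))
    if np.std(known_v) == 0:
        return np.full(len(target_xy), known_v[0])

    # empirical semivariogram
    iu = np.triu_indices(len(known_v), 1)
    h, gam = d_known[iu], 0.5 * (known_v[iu[0]] - known_v[iu[1]]) ** 2
    h_max = h.max()
    bins = np.linspace(0, h_max * 0.75, 11)
    bh, bg = [], []
    for lo, hi in zip(bins[:-1], bins[1:]):
        sel = (h > lo) & (h <= hi)
        if sel.sum() >= 3:
            bh.append(h[sel].mean())
            bg.append(gam[sel].mean())
    if len(bh) < 3:
        raise RuntimeError("too few variogram bins")

    def model(hh, sill, rng_):
        return sill * (1 - np.exp(-hh / rng_))

    (sill, vrange), _ = curve_fit(
        model, np.asarray(bh), np.asarray(bg),
        p0=[max(np.var(known_v), 1e-12), h_max / 3],
        bounds=([1e-12, 1e-6], [np.inf, np.inf]), maxfev=10_000,
    )

    cov = sill * np.exp(-d_known / vrange)
    n = len(known_v)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = cov
    A[n, :n] = A[:n, n] = 1.0
    A[n, n] = 0.0
    d_t = np.sqrt(((target_xy[:, None] - known_xy[None]) ** 2).sum(axis=2))
    rhs = np.empty((n + 1, len(target_xy)))
    rhs[:n] = sill * np.exp(-d_t.T / vrange)
    rhs[n] = 1.0
    w = np.linalg.solve(A, rhs)[:n]
    return known_v @ w


def _idw(known_xy, known_v, target_xy, power: float = 2.0):
    d = np.sqrt(((target_xy[:, None] - known_xy[None]) ** 2).sum(axis=2))
    d = np.maximum(d, 1e-9)
    w = 1.0 / d**power
    return (w * known_v[None]).sum(axis=1) / w.sum(axis=1)


# ---------------------------------------------------------------------------
# Diversity vs hit score
# ---------------------------------------------------------------------------

def correlate_ho_hitscore(
    surface: DiversitySurface,
    hit_score_grid: RasterGrid,
    localities: list[Locality],
) -> tuple[float, float, float]:
    """Pearson correlation of Ho and geoprofile hit score at the localities.

    Both rasters must share the grid. Returns (r, t, p) with
    t = r * sqrt((n-2)/(1-r^2)) and a two-sided p.
    """
    if not surface.grid.same_grid(hit_score_grid):
        raise ValueError("mismatched grids")
    ho_vals, hs_vals = [], []
    for loc in localities:
        try:
            row, col = surface.grid.cell_of(loc.x, loc.y)
        except IndexError:
            continue
        ho = surface.grid.values[row, col]
        hs = hit_score_grid.values[row, col]
        if ho != surface.grid.nodata and hs != hit_score_grid.nodata:
            ho_vals.append(ho)
            hs_vals.append(hs)
    n = len(ho_vals)
    if n < 3:
        raise ValueError("need >= 3 localities with values on both rasters")
    r = float(np.corrcoef(hs_vals, ho_vals)[0, 1])
    if abs(r) >= 1.0:
        return r, math.copysign(math.inf, r), 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return r, float(t), float(p)
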