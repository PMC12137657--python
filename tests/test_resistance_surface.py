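import itertools
import math

import numpy as np
import pytest

from invasionscape.core_io import (
    DistanceMatrix,
    GenotypeMatrix,
    Locality,
    RasterGrid,
    make_grid,
)
from invasionscape.resistance_surface import (
    CLASS_BARRIER,
    CLASS_NOT_SIGNIFICANT,
    IBDResiduals,
    cells_crossed,
    correlate_ho_hitscore,
    DiversitySurface,
    fit_ibd_residuals,
    krige_surface,
    map_resistance,
    windowed_heterozygosity,
)


def line_coords(n, spacing=1000.0):
    return {f"i{k}": (spacing * k, 0.0) for k in range(n)}


def dm_from_pairs(labels, value_fn):
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = value_fn(labels[i], labels[j])
    return DistanceMatrix(labels=labels, d=d)


class TestFitIBDResiduals:
    def test_on_curve_data_zero_residuals(self):
        coords = line_coords(6)
        labels = list(coords)

        def gd(a, b):
            d = abs(coords[a][0] - coords[b][0])
            return 0.1 + 0.02 * math.log1p(d)

        res = fit_ibd_residuals(dm_from_pairs(labels, gd), coords, d_max=1e6)
        assert np.allclose(res.residuals, 0.0, atol=1e-9)
        assert res.intercept == pytest.approx(0.1, abs=1e-9)
        assert res.slope == pytest.approx(0.02, abs=1e-9)

    def test_symmetric_deviations_scale_to_unit(self):
        coords = line_coords(6)
        labels = list(coords)
        bump = {("i0", "i1"): 0.05, ("i0", "i2"): -0.05}

        def gd(a, b):
            d = abs(coords[a][0] - coords[b][0])
            return 0.1 + 0.02 * math.log1p(d) + bump.get((a, b), 0.0)

        res = fit_ibd_residuals(dm_from_pairs(labels, gd), coords, d_max=1e6)
        # scaling by the maximum absolute residual pins the extreme at +/-1
        assert np.abs(res.residuals).max() == pytest.approx(1.0)
        assert res.residuals.max() > 0.8 and res.residuals.min() < -0.8

    def test_coefficients_match_normal_equations(self):
        rng = np.random.default_rng(0)
        coords = {f"i{k}": tuple(rng.uniform(0, 8000, 2)) for k in range(8)}
        labels = list(coords)
        gvals = {}

        def gd(a, b):
            key = (a, b)
            if key not in gvals:
                d = math.dist(coords[a], coords[b])
                gvals[key] = 0.2 + 0.01 * math.log1p(d) + rng.normal(0, 0.02)
            return gvals[key]

        genetic = dm_from_pairs(labels, gd)
        res = fit_ibd_residuals(genetic, coords, d_max=1e6)
        # closed-form OLS on the transformed predictor
        x = np.array([math.log1p(math.dist(coords[a], coords[b]))
                      for a, b in res.pairs])
        y = np.array([genetic.get(a, b) for a, b in res.pairs])
        b_hat = np.cov(x, y, ddof=0)[0, 1] / np.var(x)
        a_hat = y.mean() - b_hat * x.mean()
        assert res.slope == pytest.approx(b_hat, abs=1e-10)
        assert res.intercept == pytest.approx(a_hat, abs=1e-10)

    def test_distance_cutoff_and_pair_minimum(self):
        coords = line_coords(5)
        labels = list(coords)
        genetic = dm_from_pairs(labels, lambda a, b: 0.1)
        with pytest.raises(ValueError, match="pairs"):
            fit_ibd_residuals(genetic, coords, d_max=1500.0)


class TestCellsCrossed:
    def _supersample(self, grid, seg, n=20_000):
        (x0, y0), (x1, y1) = seg
        t = np.linspace(0, 1, n)
        xs, ys = x0 + t * (x1 - x0), y0 + t * (y1 - y0)
        cells = set()
        for x, y in zip(xs, ys):
            try:
                cells.add(grid.cell_of(x, y))
            except IndexError:
                pass
        return cells

    @pytest.mark.parametrize("seg", [
        ((50.0, 50.0), (2950.0, 2950.0)),     # main diagonal
        ((10.0, 2990.0), (2990.0, 10.0)),     # anti-diagonal
        ((100.0, 1500.0), (2900.0, 1600.0)),  # shallow slope
    ])
    def test_matches_supersampling_oracle(self, seg):
        grid = make_grid((0, 0, 3000, 3000), 1000.0)
        exact = set(cells_crossed(grid, seg))
        sampled = self._supersample(grid, seg)
        # supersampling can miss grazing corner contacts but never finds
        # extras; every extra cell must genuinely touch the segment
        assert sampled <= exact
        from shapely.geometry import LineString, box as shp_box

        line = LineString(seg)
        for row, col in exact - sampled:
            x0 = grid.x_origin + col * grid.cell_size
            y0 = grid.y_origin + (grid.n_rows - 1 - row) * grid.cell_size
            cell = shp_box(x0, y0, x0 + grid.cell_size, y0 + grid.cell_size)
            assert cell.distance(line) == pytest.approx(0.0, abs=1e-9)


class TestMapResistance:
    def _residuals(self, segments, values):
        return IBDResiduals(
            pairs=[(f"a{k}", f"b{k}") for k in range(len(segments))],
            residuals=np.asarray(values, dtype=float),
            segments=segments, intercept=0.0, slope=0.0, d_max=1e6)

    def test_zero_residuals_nowhere_significant(self):
        rng = np.random.default_rng(1)
        segs = [tuple(map(tuple, rng.uniform(0, 5000, (2, 2))))
                for _ in range(30)]
        res = self._residuals(segs, np.zeros(30))
        surf = map_resistance(res, make_grid((0, 0, 5000, 5000), 1000.0),
                              n_resample=100, seed=0)
        vals = surf.grid.values
        crossed = vals != surf.grid.nodata
        assert np.allclose(vals[crossed], 0.0)
        assert (surf.significance.values[crossed]
                == CLASS_NOT_SIGNIFICANT).all()

    def test_lone_positive_segment_classified_barrier(self):
        rng = np.random.default_rng(2)
        # a pool of near-zero residuals plus one strongly positive segment
        # crossing a remote cell on its own
        segs = [((float(x), 0.0), (float(x), 900.0))
                for x in rng.uniform(0, 4000, 100)]
        segs.append(((9500.0, 9500.0), (9900.0, 9900.0)))
        values = list(rng.normal(0, 0.05, 100)) + [1.0]
        res = self._residuals(segs, values)
        grid = make_grid((0, 0, 10_000, 10_000), 1000.0)
        surf = map_resistance(res, grid, n_resample=500, alpha=0.05, seed=3)
        row, col = grid.cell_of(9700.0, 9700.0)
        assert surf.significance.values[row, col] == CLASS_BARRIER

    def test_uncrossed_cells_are_nodata(self):
        res = self._residuals([((100.0, 100.0), (200.0, 100.0))], [0.5])
        surf = map_resistance(res, make_grid((0, 0, 3000, 3000), 1000.0),
                              n_resample=50, seed=0)
        assert surf.grid.values[0, 2] == surf.grid.nodata

    def test_classification_depends_only_on_geometry_and_values(self):
        rng = np.random.default_rng(4)
        segs = [tuple(map(tuple, rng.uniform(0, 4000, (2, 2))))
                for _ in range(25)]
        vals = rng.normal(0, 0.3, 25)
        grid = make_grid((0, 0, 4000, 4000), 800.0)
        a = map_resistance(self._residuals(segs, vals), grid,
                           n_resample=200, seed=9)
        perm = rng.permutation(25)
        b = map_resistance(self._residuals([segs[i] for i in perm],
                                           vals[perm]), grid,
                           n_resample=200, seed=9)
        assert np.array_equal(a.grid.values, b.grid.values)


def genotypes_at(points, calls_rows):
    inds = [f"i{k}" for k in range(len(points))]
    G = GenotypeMatrix(inds, [f"l{j}" for j in range(len(calls_rows[0]))],
                       np.asarray(calls_rows, dtype=np.int8),
                       {i: 1 for i in inds})
    return G, {ind: pt for ind, pt in zip(inds, points)}


class TestWindowedHeterozygosity:
    def test_exact_rarefaction_size_equals_direct_ho(self):
        pts = [(500.0, 500.0)] * 3
        calls = [[1, 0, 1], [0, 1, 2], [1, 1, 0]]
        G, coords = genotypes_at(pts, calls)
        grid = make_grid((0, 0, 1000, 1000), 1000.0)
        surf = windowed_heterozygosity(G, coords, grid, window=1,
                                       rarefaction_n=3, seed=0)
        # direct Ho: per-locus het fractions (2/3, 2/3, 1/3), mean = 5/9
        assert surf.grid.values[0, 0] == pytest.approx(5 / 9)

    def test_fully_heterozygous_individuals_give_one(self):
        pts = [(500.0, 500.0)] * 4
        calls = [[1, 1, 1]] * 4
        G, coords = genotypes_at(pts, calls)
        grid = make_grid((0, 0, 1000, 1000), 1000.0)
        surf = windowed_heterozygosity(G, coords, grid, window=1,
                                       rarefaction_n=2, n_draws=10, seed=0)
        assert surf.grid.values[0, 0] == pytest.approx(1.0)

    def test_sparse_window_left_nodata(self):
        pts = [(500.0, 500.0)] * 2
        calls = [[1, 0], [0, 1]]
        G, coords = genotypes_at(pts, calls)
        grid = make_grid((0, 0, 3000, 1000), 1000.0)
        surf = windowed_heterozygosity(G, coords, grid, window=1,
                                       rarefaction_n=3, seed=0)
        assert (surf.grid.values == grid.nodata).all()

    def test_rarefied_mean_matches_exhaustive_enumeration(self):
        pts = [(500.0, 500.0)] * 4
        calls = [[1, 0], [0, 0], [1, 2], [1, 1]]
        G, coords = genotypes_at(pts, calls)
        grid = make_grid((0, 0, 1000, 1000), 1000.0)
        surf = windowed_heterozygosity(G, coords, grid, window=1,
                                       rarefaction_n=3, n_draws=4000, seed=1)
        hets = np.asarray(calls) == 1
        subsets = list(itertools.combinations(range(4), 3))
        exact = np.mean([hets[list(s)].mean(axis=0).mean() for s in subsets])
        assert surf.grid.values[0, 0] == pytest.approx(exact, abs=0.02)

    def test_small_rarefaction_rejected(self):
        G, coords = genotypes_at([(0.0, 0.0)] * 2, [[1], [0]])
        grid = make_grid((0, 0, 1000, 1000), 1000.0)
        with pytest.raises(ValueError, match="rarefaction"):
            windowed_heterozygosity(G, coords, grid, rarefaction_n=1, seed=0)


class TestKriging:
    def _surface(self, vals, nodata=-9999.0):
        grid = RasterGrid(0.0, 0.0, 1000.0, np.asarray(vals, dtype=float),
                          nodata=nodata)
        return DiversitySurface(grid=grid, window=3, rarefaction_n=2)

    def test_constant_field_stays_constant(self):
        vals = np.full((5, 5), -9999.0)
        vals[::2, ::2] = 0.25
        filled = krige_surface(self._surface(vals))
        assert np.allclose(filled.grid.values, 0.25)

    def test_defined_cells_retained_exactly(self):
        rng = np.random.default_rng(5)
        vals = np.full((6, 6), -9999.0)
        mask = rng.random((6, 6)) < 0.5
        vals[mask] = rng.uniform(0.1, 0.3, mask.sum())
        partial = self._surface(vals)
        filled = krige_surface(partial)
        assert np.array_equal(filled.grid.values[mask], vals[mask])
        assert (filled.grid.values != -9999.0).all()

    def test_linear_trend_interpolated_midpoints(self):
        # plane f(x, y) = 0.1 + x / 100 km; leave interior columns undefined
        vals = np.full((5, 9), -9999.0)
        for col in (0, 1, 4, 7, 8):
            for row in range(5):
                vals[row, col] = 0.1 + (col + 0.5) / 100.0
        filled = krige_surface(self._surface(vals))
        for col in (2, 3, 5, 6):
            plane = 0.1 + (col + 0.5) / 100.0
            got = filled.grid.values[2, col]
            assert got == pytest.approx(plane, rel=0.05)

    def test_too_few_cells_rejected(self):
        vals = np.full((3, 3), -9999.0)
        vals[0, 0] = vals[1, 1] = 0.2
        with pytest.raises(ValueError, match="defined"):
            krige_surface(self._surface(vals))


class TestCorrelateHoHitscore:
    def _grids(self, ho_vals, hs_vals):
        grid = make_grid((0, 0, 5000, 1000), 1000.0)
        ho = DiversitySurface(grid=grid.copy_with(np.asarray(ho_vals, float)),
                              window=3, rarefaction_n=2)
        hs = grid.copy_with(np.asarray(hs_vals, float))
        return ho, hs

    locs = [Locality(i + 1, 500.0 + 1000.0 * i, 500.0) for i in range(5)]

    def test_perfect_linear_relation(self):
        hs = [[0.1, 0.2, 0.3, 0.4, 0.5]]
        ho = [[0.12, 0.14, 0.16, 0.18, 0.20]]
        surf, hsg = self._grids(ho, hs)
        r, t, p = correlate_ho_hitscore(surf, hsg, self.locs)
        assert r == pytest.approx(1.0)

    def test_t_statistic_closed_form(self):
        hs = [[0.1, 0.25, 0.3, 0.45, 0.5]]
        ho = [[0.22, 0.18, 0.20, 0.15, 0.13]]
        surf, hsg = self._grids(ho, hs)
        r, t, p = correlate_ho_hitscore(surf, hsg, self.locs)
        assert t == pytest.approx(r * math.sqrt(3 / (1 - r**2)), rel=1e-12)
        from scipy import stats as sps

        assert p == pytest.approx(2 * sps.t.sf(abs(t), df=3), rel=1e-12)

    def test_mismatched_grids_rejected(self):
        surf, _ = self._grids([[0.1] * 5], [[0.2] * 5])
        other = make_grid((0, 0, 5000, 1000), 500.0)
        with pytest.raises(ValueError, match="grid"):
            correlate_ho_hitscore(surf, other, self.locs)

    def test_independent_fields_give_uniform_p(self):
        rng = np.random.default_rng(7)
        grid = make_grid((0, 0, 10_000, 1000), 1000.0)
        locs = [Locality(i + 1, 500.0 + 1000.0 * i, 500.0) for i in range(10)]
        ps = []
        for rep in range(100):
            ho = DiversitySurface(
                grid=grid.copy_with(rng.random((1, 10))), window=3,
                rarefaction_n=2)
            hs = grid.copy_with(rng.random((1, 10)))
            ps.append(correlate_ho_hitscore(ho, hs, locs)[2])
        assert 0.3 < np.mean(np.array(ps) < 0.5) < 0.7
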