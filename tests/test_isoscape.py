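"""Correlations, variogram fitting, ordinary kriging, masks, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from plasmascape.errors import (DegenerateHullError, InsufficientDataError,
                                InsufficientIndividualsError, NoOverlapError,
                                UndefinedCorrelationError)
from plasmascape.grids import GridSpec
from plasmascape.isoscape import (IsoscapeSurface, OrdinaryKriging, Variogram,
                                  bootstrap_guild_isoscape, build_mask,
                                  correlate, difference_surface, fit_variogram,
                                  krige, mask_cells)


class TestCorrelate:
    def test_exact_published_gradient(self):
        lat = np.array([-55, -50, -48, -45, -40], float)
        res = correlate(0.21 * lat - 11.25, lat, "lat")
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(0.21, abs=1e-12)
        assert res.intercept == pytest.approx(-11.25, abs=1e-9)

    def test_zero_covariance(self):
        res = correlate([1.0, 0.0, 1.0], [-50.0, -48.0, -46.0], "lat")
        assert res.r == pytest.approx(0.0, abs=1e-12)

    def test_duplication_keeps_r_shrinks_p(self):
        lat = np.array([-55, -50, -44, -41, -39.0])
        vals = 0.2 * lat - 11 + np.array([0.3, -0.2, 0.1, -0.4, 0.2])
        a = correlate(vals, lat)
        b = correlate(np.tile(vals, 2), np.tile(lat, 2))
        assert b.r == pytest.approx(a.r)
        assert b.slope == pytest.approx(a.slope)
        assert b.p < a.p

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            correlate([1.0, 1.0, 1.0], [-50.0, -48.0, -46.0])

    def test_sign_consistency(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = -0.5 * x + rng.normal(scale=0.3, size=30)
        res = correlate(y, x)
        assert np.sign(res.r) == np.sign(res.slope)


class TestVariogram:
    def test_pure_nugget_process(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 10, (200, 2))
        values = rng.normal(0.0, 1.0, 200)
        vg = fit_variogram(coords, values)
        assert vg.nugget == pytest.approx(values.var(ddof=1), rel=0.25)
        assert vg.psill <= 0.25 * values.var(ddof=1)

    def test_trend_gives_monotone_semivariance(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 10, (120, 2))
        values = 0.5 * coords[:, 1]  # noiseless linear trend
        vg = fit_variogram(coords, values)
        gam = vg.bins["gamma"].to_numpy()
        # gamma grows ~h^2 for a trend: overwhelmingly increasing bins
        assert np.mean(np.diff(gam) > 0) > 0.8

    def test_two_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_variogram(np.array([[0.0, 0], [1, 1]]), np.array([1.0, 2.0]))


def _brute_force_ok(coords, values, vg, targets):
    """Independent dense solve of the ordinary kriging equations per target."""
    n = len(values)
    K = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            h = np.hypot(*(coords[i] - coords[j]))
            K[i, j] = vg.covariance(h)
    K[:n, n] = 1.0
    K[n, :n] = 1.0
    out = []
    for t in targets:
        rhs = np.zeros(n + 1)
        for i in range(n):
            rhs[i] = vg.covariance(np.hypot(*(coords[i] - t)))
        rhs[n] = 1.0
        sol = np.linalg.solve(K, rhs)
        out.append(sol[:n] @ values)
    return np.array(out)


class TestKriging:
    GRID = GridSpec(0.5, 0.0, 0.0, 6, 6)

    def test_constant_data_reproduced(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 3, (8, 2))
        vg = Variogram("spherical", 0.1, 1.0, 2.0)
        surf = krige(coords, np.full(8, -21.0), self.GRID, vg=vg)
        np.testing.assert_allclose(surf.values, -21.0, atol=1e-8)

    def test_exact_at_sample_locations(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 3, (7, 2))
        values = rng.normal(-21, 1, 7)
        vg = Variogram("exponential", 0.0, 1.0, 1.5)
        ok = OrdinaryKriging(variogram=vg).fit(coords, values)
        np.testing.assert_allclose(ok.predict(coords), values, atol=1e-6)

    def test_exact_at_samples_with_nugget(self):
        # micro-scale nugget convention: data still honoured exactly
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 3, (7, 2))
        values = rng.normal(-21, 1, 7)
        vg = Variogram("spherical", 0.3, 1.0, 1.5)
        ok = OrdinaryKriging(variogram=vg).fit(coords, values)
        np.testing.assert_allclose(ok.predict(coords), values, atol=1e-6)

    @pytest.mark.parametrize("model", ["spherical", "exponential", "gaussian"])
    def test_brute_force_oracle(self, model):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 3, (9, 2))
        values = rng.normal(-21, 1, 9)
        vg = Variogram(model, 0.2, 1.3, 1.8)
        ok = OrdinaryKriging(variogram=vg).fit(coords, values)
        lon2d, lat2d = self.GRID.meshgrid_centers()
        targets = np.column_stack([lon2d.ravel(), lat2d.ravel()])
        mine = ok.predict(targets)
        oracle = _brute_force_ok(coords, values, vg, targets)
        np.testing.assert_allclose(mine, oracle, atol=1e-8)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(6)
        coords = rng.uniform(0, 3, (10, 2))
        values = rng.normal(0, 1, 10)
        ok = OrdinaryKriging(variogram=Variogram("spherical", 0.1, 1.0, 2.0))
        ok.fit(coords, values)
        lon2d, lat2d = self.GRID.meshgrid_centers()
        sol = ok.kriging_weights(np.column_stack([lon2d.ravel(), lat2d.ravel()]))
        np.testing.assert_allclose(sol[:-1].sum(axis=0), 1.0, atol=1e-9)

    def test_duplicate_coordinates_averaged(self):
        coords = np.array([[0.0, 0], [0, 0], [1, 1], [2, 0], [1, 2]])
        values = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
        ok = OrdinaryKriging(variogram=Variogram("spherical", 0.0, 1.0, 2.0))
        ok.fit(coords, values)
        assert len(ok.y_) == 4
        assert ok.predict(np.array([[0.0, 0.0]]))[0] == pytest.approx(2.0, abs=1e-6)


class TestMask:
    def test_dilated_unit_square_membership(self):
        square = [(0, 0), (1, 0), (1, 1), (0, 1)]
        poly = build_mask(square, 0.5)
        assert poly.contains(Point(0.5, 1.4))
        assert not poly.contains(Point(0.5, 1.6))

    def test_single_point_degenerate(self):
        with pytest.raises(DegenerateHullError):
            build_mask([(1.0, 1.0), (1.0, 1.0)], 0.5)

    def test_zero_buffer_equals_hull(self):
        square = [(0, 0), (1, 0), (1, 1), (0, 1)]
        poly = build_mask(square, 0.0)
        assert poly.area == pytest.approx(1.0)

    def test_mask_cells_centers(self):
        grid = GridSpec(0.5, 0.0, 0.0, 4, 4)
        poly = build_mask([(0, 0), (2, 0), (2, 2), (0, 2)], 0.0)
        cells = mask_cells(grid, poly)
        assert cells.all()  # all 16 centres inside the 2x2 square


class TestDifference:
    @staticmethod
    def _surface(values, west=0.0, south=0.0):
        grid = GridSpec(0.5, west, south, values.shape[1], values.shape[0])
        return IsoscapeSurface(grid, values, np.isfinite(values))

    def test_self_difference_zero(self):
        a = self._surface(np.random.default_rng(0).normal(size=(4, 4)))
        d = difference_surface(a, a)
        np.testing.assert_allclose(d.values[d.mask], 0.0)

    def test_constant_offset(self):
        vals = np.random.default_rng(1).normal(size=(4, 4))
        a = self._surface(vals + 1.0)
        b = self._surface(vals)
        d = difference_surface(a, b)
        np.testing.assert_allclose(d.values[d.mask], 1.0)

    def test_partial_overlap_aligned(self):
        vals = np.ones((4, 4))
        a = self._surface(vals * 5.0, west=0.0)
        b = self._surface(vals * 2.0, west=1.0)  # shares a 2x4 window
        d = difference_surface(a, b)
        np.testing.assert_allclose(d.values[d.mask], 3.0)
        assert d.mask.sum() == 8

    def test_disjoint_masks_error(self):
        a = self._surface(np.ones((3, 3)), west=0.0)
        b = self._surface(np.ones((3, 3)), west=10.0)
        with pytest.raises(NoOverlapError):
            difference_surface(a, b)


class TestBootstrap:
    @staticmethod
    def _species_frames(seed=0, n=6, n_species=3, slope=0.0, noise=0.0,
                        const=-21.0):
        rng = np.random.default_rng(seed)
        frames = {}
        for s in range(n_species):
            lon = rng.uniform(0, 4, n)
            lat = rng.uniform(-50, -44, n)
            frames[f"sp{s}"] = pd.DataFrame({
                "lon": lon, "lat": lat,
                "d13c": const + slope * lat + rng.normal(0, noise, n)})
        return frames

    def test_degenerate_single_replicate_equals_pooled(self):
        frames = self._species_frames(noise=0.5, slope=0.2)
        surf, _ = bootstrap_guild_isoscape(frames, "d13c", k_per_species=6,
                                           B=1, seed=0, cell_size=0.5,
                                           buffer_deg=0.5)
        pooled = pd.concat(frames.values(), ignore_index=True)
        ref = krige(pooled[["lon", "lat"]].to_numpy(),
                    pooled["d13c"].to_numpy(), surf.grid, mask=surf.mask)
        np.testing.assert_allclose(surf.values[surf.mask],
                                   ref.values[ref.mask], atol=1e-10)

    def test_constant_field_constant_mean(self):
        frames = self._species_frames()
        surf, _ = bootstrap_guild_isoscape(frames, "d13c", k_per_species=4,
                                           B=5, seed=1, cell_size=0.5,
                                           buffer_deg=0.5)
        np.testing.assert_allclose(surf.values[surf.mask], -21.0, atol=1e-7)

    def test_mean_within_envelope(self):
        frames = self._species_frames(noise=0.5, slope=0.2, seed=2)
        surf, (lo, hi) = bootstrap_guild_isoscape(frames, "d13c",
                                                  k_per_species=4, B=12,
                                                  seed=3, cell_size=0.5,
                                                  buffer_deg=0.5)
        m = surf.mask
        assert np.all(surf.values[m] >= lo[m] - 1e-9)
        assert np.all(surf.values[m] <= hi[m] + 1e-9)

    def test_insufficient_individuals(self):
        frames = self._species_frames(n=3)
        with pytest.raises(InsufficientIndividualsError):
            bootstrap_guild_isoscape(frames, "d13c", k_per_species=5, B=2,
                                     seed=0)

    def test_reproducible_under_seed(self):
        frames = self._species_frames(noise=0.5, slope=0.2, seed=4)
        a, _ = bootstrap_guild_isoscape(frames, "d13c", 4, B=4, seed=9,
                                        cell_size=0.5, buffer_deg=0.5)
        b, _ = bootstrap_guild_isoscape(frames, "d13c", 4, B=4, seed=9,
                                        cell_size=0.5, buffer_deg=0.5)
        np.testing.assert_array_equal(a.values, b.values)


def test_gradient_sign_preserved_north_south():
    """A kriged surface from a clear latitudinal gradient keeps the sign of
    the generating slope between its northern and southern thirds."""
    rng = np.random.default_rng(11)
    lon = rng.uniform(0, 6, 30)
    lat = rng.uniform(-54, -40, 30)
    vals = 0.21 * lat - 12.0 + rng.normal(0, 0.3, 30)
    grid = GridSpec(0.5, 0.0, -55.0, 12, 30)
    surf = krige(np.column_stack([lon, lat]), vals, grid)
    lat2d = grid.meshgrid_centers()[1]
    north = surf.values[lat2d > -44].mean()
    south = surf.values[lat2d < -50].mean()
    assert north > south
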