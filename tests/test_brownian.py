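import warnings
from datetime import timedelta

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm
from shapely.geometry import Polygon, box

from sealmove.brownian import (
    BridgeParams,
    BrownianBridgeUD,
    Isopleth,
    UDGrid,
    bb_step_density,
    bb_ud,
    bridge_loglik,
    estimate_sig1,
    isopleth,
    make_grid,
    overlap_fraction,
    subtract_land,
)

from .conftest import T0, make_track


def gaussian_ud(sd=2.0, cell=0.25, half_extent=12.0):
    """Isotropic Gaussian UD grid used by the quantile-ratio checks."""
    n = int(2 * half_extent / cell) + 1
    xs = -half_extent + cell * np.arange(n)
    p = np.outer(norm.pdf(xs, scale=sd), norm.pdf(xs, scale=sd))
    g = UDGrid(x0=float(xs[0]), y0=float(xs[0]), cell_km=cell, probs=p / p.sum())
    return g


class TestStepDensity:
    def test_total_mass_is_duration(self):
        grid = make_grid(np.array([[0.0, 0.0], [5.0, 5.0]]), 0.5, 12.0)
        d = bb_step_density((0, 0), (5, 5), 0.0, 4.0, BridgeParams(sig1=1.0),
                            grid, 0.5, 0.5)
        # quadrature average integrates to 1; weighting multiplies by T
        assert d.sum() == pytest.approx(4.0, rel=1e-6)

    def test_variance_limits_at_endpoints(self):
        # alpha -> 0: variance -> sig2_1^2 (pure observation error). Check via
        # the formula with a 1-point quadrature pinned near alpha = 0.
        T, sig1, s1, s2 = 4.0, 1.5, 0.7, 2.0
        a = 1e-9
        var = T * a * (1 - a) * sig1**2 + (1 - a) ** 2 * s1**2 + a**2 * s2**2
        assert var == pytest.approx(s1**2, rel=1e-6)

    def test_stationary_zero_sig1_mixture_variance(self):
        # z_i = z_{i+1}, sig1 = 0: mixture of centered Gaussians with variance
        # ((1-a)^2 + a^2) s^2, which lies in [s^2/2, s^2]
        s = 1.0
        grid = make_grid(np.array([[0.0, 0.0]]), 0.2, 8.0)
        d = bb_step_density((0, 0), (0, 0), 0.0, 6.0, BridgeParams(sig1=0.0),
                            grid, s, s)
        d = d / d.sum()
        ny, nx = d.shape
        xs = grid.x0 + grid.cell_km * np.arange(nx)
        var_emp = float((d.sum(axis=0) * xs**2).sum())
        assert s**2 / 2 <= var_emp <= s**2 + 0.01

    def test_matches_brute_force_integration(self):
        """Analytic quadrature vs dense numerical integration of the bridge."""
        grid = make_grid(np.array([[0.0, 0.0], [4.0, 2.0]]), 0.4, 8.0)
        params = BridgeParams(sig1=1.2, alpha_steps=200)
        got = bb_step_density((0, 0), (4, 2), 0.0, 5.0, params, grid, 0.8, 1.1)
        got = got / got.sum()

        # oracle: midpoint-subdivided cells, same dense alpha rule, direct
        # pointwise bivariate normal evaluation
        ny, nx = grid.probs.shape
        sub = 12
        h = grid.cell_km
        offs = (np.arange(sub) + 0.5) / sub * h - h / 2
        xs = grid.x0 + h * np.arange(nx)
        ys = grid.y0 + h * np.arange(ny)
        oracle = np.zeros((ny, nx))
        m = 200
        z1, z2 = np.array([0.0, 0.0]), np.array([4.0, 2.0])
        T = 5.0
        for a in (np.arange(m) + 0.5) / m:
            mu = (1 - a) * z1 + a * z2
            var = (T * a * (1 - a) * params.sig1**2
                   + (1 - a) ** 2 * 0.8**2 + a**2 * 1.1**2)
            fx = np.zeros(nx)
            fy = np.zeros(ny)
            for o in offs:
                fx += np.exp(-0.5 * (xs + o - mu[0]) ** 2 / var)
                fy += np.exp(-0.5 * (ys + o - mu[1]) ** 2 / var)
            fx *= h / sub
            fy *= h / sub
            oracle += np.outer(fy, fx) / (2 * np.pi * var)
        oracle = oracle / oracle.sum()
        assert np.abs(got - oracle).sum() < 1e-4

    def test_nonpositive_duration_skipped_with_warning(self):
        grid = make_grid(np.array([[0.0, 0.0]]), 1.0, 5.0)
        with pytest.warns(UserWarning, match="non-positive"):
            d = bb_step_density((0, 0), (1, 1), 3.0, 3.0, BridgeParams(), grid,
                                1.0, 1.0)
        assert d.sum() == 0.0


class TestSig1Estimation:
    def test_parameter_recovery_brownian_track(self):
        rng = np.random.default_rng(42)
        sig1_true = 2.0
        n = 500
        xy = np.vstack([[0, 0],
                        np.cumsum(rng.normal(0, sig1_true, (n - 1, 2)), axis=0)])
        trk = pd.DataFrame({
            "timestamp": [T0 + timedelta(hours=h) for h in range(n)],
            "lon": xy[:, 0] / (111.195 * np.cos(np.radians(58.0))),
            "lat": 58.0 + xy[:, 1] / 111.195,
        })
        est = estimate_sig1(trk, error_model={"3": 0.01},
                            search_interval=(1e-3, 20.0))
        assert est == pytest.approx(sig1_true, rel=0.2)

    def test_coincident_fixes_hit_lower_bound(self):
        trk = make_track([(0.0, 58.0)] * 7)
        with pytest.warns(UserWarning, match="boundary"):
            est = estimate_sig1(trk, search_interval=(0.01, 10.0))
        assert est < 0.02

    def test_larger_sig2_absorbs_apparent_motion(self, rng):
        n = 101
        xy = np.vstack([[0, 0], np.cumsum(rng.normal(0, 1.0, (n - 1, 2)), axis=0)])
        t = np.arange(n, dtype=float)
        ll_small = [bridge_loglik(s, xy, t, np.full(n, 0.1)) for s in (0.5, 1.0, 2.0)]
        ll_big = [bridge_loglik(s, xy, t, np.full(n, 1.5)) for s in (0.5, 1.0, 2.0)]
        # with inflated observation error the likelihood prefers smaller sig1
        assert np.argmax(ll_big) <= np.argmax(ll_small)

    def test_too_few_fixes_rejected(self):
        with pytest.raises(ValueError, match="3 fixes"):
            estimate_sig1(make_track([(0, 58), (0.1, 58)]))


class TestUD:
    def test_single_step_equals_normalized_step_density(self):
        trk = make_track([(0.0, 58.0), (0.05, 58.02)], hours=[0, 3])
        params = BridgeParams(sig1=1.0)
        uds = bb_ud(trk, params, cell_km=0.5)
        assert len(uds) == 1
        assert uds[0].probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_every_ud_sums_to_one_and_isopleths_nest(self, rng):
        n = 80
        lon = -157 + np.cumsum(rng.normal(0, 0.02, n))
        lat = 58 + np.cumsum(rng.normal(0, 0.015, n))
        trk = make_track(list(zip(lon, lat)), hours=np.arange(n) * 10.0)
        uds = bb_ud(trk, BridgeParams(sig1=1.5), cell_km=1.0)
        assert len(uds) >= 2  # spans month boundaries at 5-hr spacing
        for ud in uds:
            assert ud.probs.sum() == pytest.approx(1.0, abs=1e-6)
            i50, i90 = isopleth(ud, 0.5), isopleth(ud, 0.9)
            assert (i50.mask & ~i90.mask).sum() == 0
            assert i50.area_km2 <= i90.area_km2

    def test_months_partition_by_step_start(self):
        # step starting Oct 31 23:00, ending Nov 1 01:00 -> October UD
        trk = make_track([(0.0, 58.0), (0.01, 58.0), (0.02, 58.0)],
                         hours=[0.0, 742.0, 744.5])  # Oct 1 .. Nov 1
        uds = bb_ud(trk, BridgeParams(sig1=1.0, max_gap_hr=1000.0), cell_km=1.0)
        months = {u.month for u in uds}
        assert months == {"2000-10"}

    def test_sparse_month_omitted_with_warning(self):
        trk = make_track([(0.0, 58.0), (0.01, 58.0), (0.02, 58.0)],
                         hours=[0.0, 5.0, 24 * 40.0])
        with pytest.warns(UserWarning, match="fewer than 2"):
            uds = bb_ud(trk, BridgeParams(sig1=1.0), cell_km=1.0)
        assert {u.month for u in uds} == {"2000-10"}

    def test_quadrature_convergence(self):
        trk = make_track([(0.0, 58.0), (0.04, 58.03), (0.0, 58.06)],
                         hours=[0, 4, 8])
        ud1 = bb_ud(trk, BridgeParams(sig1=1.0, alpha_steps=25), cell_km=0.5)[0]
        ud2 = bb_ud(trk, BridgeParams(sig1=1.0, alpha_steps=50), cell_km=0.5)[0]
        assert 0.5 * np.abs(ud1.probs - ud2.probs).sum() < 1e-3

    def test_grid_refinement_stability(self):
        trk = make_track([(0.0, 58.0), (0.04, 58.03), (0.08, 58.0)],
                         hours=[0, 4, 8])
        a1 = isopleth(bb_ud(trk, BridgeParams(sig1=1.0), cell_km=0.5)[0], 0.5)
        a2 = isopleth(bb_ud(trk, BridgeParams(sig1=1.0), cell_km=0.25)[0], 0.5)
        assert a2.area_km2 == pytest.approx(a1.area_km2, rel=0.05)

    def test_estimator_api(self):
        trk = make_track([(0.0, 58.0), (0.03, 58.02), (0.06, 58.0),
                          (0.03, 57.98)], hours=[0, 3, 6, 9])
        est = BrownianBridgeUD(sig1=1.0, cell_km=1.0).fit(trk)
        assert est.sig1_ == 1.0
        assert ("2000-10", 0.5) in est.isopleths_


class TestIsopleth:
    def test_level_one_takes_all_nonzero_cells(self):
        ud = gaussian_ud(sd=1.0, cell=0.5, half_extent=4.0)
        iso = isopleth(ud, 1.0)
        assert iso.mask.sum() == (ud.probs > 0).sum()

    def test_uniform_ud_half_level(self):
        p = np.full((10, 10), 0.01)
        ud = UDGrid(0.0, 0.0, 1.0, p)
        iso = isopleth(ud, 0.5)
        assert iso.mask.sum() == 50
        # deterministic tie-break: repeat gives the identical mask
        assert np.array_equal(iso.mask, isopleth(ud, 0.5).mask)

    def test_invalid_level_rejected(self):
        ud = gaussian_ud()
        for lev in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                isopleth(ud, lev)

    def test_gaussian_area_ratio_matches_chi2_quantiles(self):
        ud = gaussian_ud(sd=2.0, cell=0.25, half_extent=14.0)
        a50 = isopleth(ud, 0.5).area_km2
        a90 = isopleth(ud, 0.9).area_km2
        assert a90 / a50 == pytest.approx(np.log(0.10) / np.log(0.50), rel=0.05)


class TestLandAndOverlap:
    def _square_iso(self, n=10, cell=1.0):
        mask = np.zeros((n + 4, n + 4), bool)
        mask[2:2 + n, 2:2 + n] = True
        grid = UDGrid(0.0, 0.0, cell, np.ones((n + 4, n + 4)))
        return Isopleth(0.5, mask, cell, float(mask.sum() * cell**2), grid=grid)

    # land polygons are given in lon/lat degrees; the test grids sit at the
    # default projection center (0, 0) where 1 degree is ~111.195 km
    DEG = 1.0 / 111.195

    def test_disjoint_land_leaves_area(self):
        iso = self._square_iso()
        far = box(5.0, 5.0, 6.0, 6.0)
        out = subtract_land(iso, far)
        assert out.area_km2_land_free == pytest.approx(iso.area_km2)

    def test_contained_in_land_zero_area(self):
        iso = self._square_iso()
        out = subtract_land(iso, box(-1.0, -1.0, 1.0, 1.0))
        assert out.area_km2_land_free == pytest.approx(0.0, abs=1e-6)

    def test_half_covered_square(self):
        iso = self._square_iso(n=10, cell=1.0)
        # cover y >= 6.5 km of the 10x10 block (cells at y centers 2..11 km)
        land = box(-20 * self.DEG, 6.5 * self.DEG, 30 * self.DEG, 40 * self.DEG)
        out = subtract_land(iso, land)
        assert out.area_km2_land_free == pytest.approx(iso.area_km2 / 2.0,
                                                       abs=1.0 * 10)

    def test_invalid_polygon_rejected(self):
        iso = self._square_iso()
        bad = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])  # bowtie
        with pytest.raises(ValueError, match="invalid"):
            subtract_land(iso, bad)

    def test_overlap_identical_disjoint_contained(self):
        a = self._square_iso(n=10)
        assert overlap_fraction(a, a) == (1.0, 1.0)
        b = self._square_iso(n=10)
        b.mask = np.zeros_like(b.mask)
        b.mask[0:2, 0:2] = True
        assert overlap_fraction(a, b) == (0.0, 0.0)
        # a strict subset covering 25% of the larger region
        c = self._square_iso(n=10)
        c.mask = np.zeros_like(c.mask)
        c.mask[2:7, 2:7] = True
        fr = overlap_fraction(c, a)
        assert fr == (1.0, 0.25)

    def test_mismatched_grids_rejected(self):
        a = self._square_iso(n=10)
        b = self._square_iso(n=12)
        with pytest.raises(ValueError, match="mismatched"):
            overlap_fraction(a, b)
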