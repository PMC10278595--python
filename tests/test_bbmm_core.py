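"""Brownian bridge core: likelihood fitting, density construction,
mass conservation, isopleth extraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import ndtr

from ovitrack.bbmm_core import (
    BBMMParams,
    GridSpec,
    UDSurface,
    bridge_density,
    compute_ud,
    estimate_sigma1,
    isopleth,
)
from ovitrack.config import BBMMConfig
from ovitrack.synthetic_data import (
    config_for_strategy,
    simulate_brownian_track,
    simulate_track,
)

ORIGIN = (450_000.0, 6_550_000.0)


def small_grid(pad=1200.0, cell=50.0):
    return GridSpec.covering(
        ORIGIN[0], ORIGIN[1], ORIGIN[0] + 400, ORIGIN[1] + 250, cell, pad
    )


class TestBridgeDensity:
    def test_zero_motion_limit_is_location_error_blob(self):
        """With coincident fixes and negligible motion variance the
        bridge collapses to a location-error blob centred on the point:
        unit mass, peak at the fix, and second moment equal to the
        time-average of the error variance profile (2/3) * sigma2^2."""
        sigma2 = 60.0
        n_alpha = 10
        params = BBMMParams(sigma1_m=1e-9, sigma2_m=sigma2)
        grid = small_grid()
        out = bridge_density(
            ORIGIN, ORIGIN, 3600.0, params, grid, n_alpha=n_alpha
        )
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
        j, i = np.unravel_index(np.argmax(out), out.shape)
        cx = grid.x0 + (i + 0.5) * grid.cell_m
        cy = grid.y0 + (j + 0.5) * grid.cell_m
        assert np.hypot(cx - ORIGIN[0], cy - ORIGIN[1]) <= grid.cell_m
        alphas = (np.arange(n_alpha) + 0.5) / n_alpha
        # cell-binned second moment carries Sheppard's correction c^2/12
        expected_var = (
            sigma2**2 * np.mean((1 - alphas) ** 2 + alphas**2)
            + grid.cell_m**2 / 12.0
        )
        xs = grid.x0 + (np.arange(grid.nx) + 0.5) * grid.cell_m
        var_x = (out.sum(axis=0) * (xs - ORIGIN[0]) ** 2).sum()
        assert var_x == pytest.approx(expected_var, rel=0.02)

    def test_generic_pair_matches_dense_oracle(self, bridge_oracle):
        params = BBMMParams(sigma1_m=3.5, sigma2_m=30.0)
        za = ORIGIN
        zb = (ORIGIN[0] + 400.0, ORIGIN[1] + 250.0)
        grid = small_grid()
        ora = bridge_oracle(za, zb, 7200.0, params, grid)
        imp = bridge_density(za, zb, 7200.0, params, grid, n_alpha=1000)
        assert np.abs(imp - ora).max() < 1e-6

    def test_default_alpha_resolution_stays_close_to_oracle(
        self, bridge_oracle
    ):
        params = BBMMParams(sigma1_m=3.5, sigma2_m=30.0)
        za = ORIGIN
        zb = (ORIGIN[0] + 400.0, ORIGIN[1] + 250.0)
        grid = small_grid()
        ora = bridge_oracle(za, zb, 7200.0, params, grid, n_alpha=1000)
        imp = bridge_density(za, zb, 7200.0, params, grid, n_alpha=10)
        assert np.abs(imp - ora).max() < 5e-3

    def test_unit_mass_on_padded_grid(self):
        params = BBMMParams(sigma1_m=2.0, sigma2_m=30.0)
        grid = small_grid(pad=2000.0)
        out = bridge_density(
            ORIGIN, (ORIGIN[0] + 400, ORIGIN[1]), 7200.0, params, grid
        )
        assert out.sum() == pytest.approx(1.0, abs=1e-6)


class TestComputeUD:
    def test_two_fixes_equal_single_bridge(self):
        params = BBMMParams(sigma1_m=2.0, sigma2_m=30.0)
        x = np.array([ORIGIN[0], ORIGIN[0] + 400])
        y = np.array([ORIGIN[1], ORIGIN[1] + 250])
        t = np.array([0.0, 7200.0])
        ud = compute_ud(x, y, t, params)
        single = bridge_density(
            (x[0], y[0]), (x[1], y[1]), 7200.0, params, ud.grid,
            n_alpha=BBMMConfig().n_alpha,
        )
        np.testing.assert_allclose(ud.mass, single, atol=1e-12)

    def test_track_ud_matches_brute_force_oracle(self, bridge_oracle):
        """A 10-fix random-walk UD agrees cell-wise with the dense
        quadrature reference."""
        rng = np.random.default_rng(5)
        n = 10
        x = ORIGIN[0] + np.cumsum(rng.normal(0, 150, n))
        y = ORIGIN[1] + np.cumsum(rng.normal(0, 150, n))
        t = np.arange(n) * 7200.0
        params = BBMMParams(sigma1_m=2.5, sigma2_m=30.0)
        cfg = BBMMConfig(n_alpha=1000)
        ud = compute_ud(x, y, t, params, cfg)
        ora = np.zeros_like(ud.mass)
        for i in range(n - 1):
            ora += bridge_oracle(
                (x[i], y[i]), (x[i + 1], y[i + 1]), 7200.0, params, ud.grid
            )
        ora /= n - 1
        assert np.abs(ud.mass - ora).max() < 1e-6

    def test_mass_conservation(self):
        cfg = config_for_strategy("RESIDENT", 2)
        track, _ = simulate_track(cfg)
        seg = track.fixes.iloc[:300]
        params = BBMMParams(sigma1_m=2.0, sigma2_m=30.0)
        t = seg["t"].to_numpy().astype("datetime64[s]").astype(float)
        ud = compute_ud(seg["x"].to_numpy(), seg["y"].to_numpy(), t, params)
        assert ud.total_mass() == pytest.approx(1.0, abs=1e-6)

    def test_mode_near_residence_centroid(self):
        """A tight residence cloud's UD mode lands within two cells of
        the true centroid (looser jitter only blurs, never shifts)."""
        for seed in range(1, 11):
            cfg = config_for_strategy(
                "RESIDENT", seed, residence_sd_m=50.0
            )
            track, gt = simulate_track(cfg)
            seg = track.fixes.iloc[:500]
            t = seg["t"].to_numpy().astype("datetime64[s]").astype(float)
            params = BBMMParams(sigma1_m=1.0, sigma2_m=30.0)
            ud = compute_ud(seg["x"].to_numpy(), seg["y"].to_numpy(), t, params)
            j, i = np.unravel_index(np.argmax(ud.mass), ud.mass.shape)
            cx = ud.grid.x0 + (i + 0.5) * ud.grid.cell_m
            cy = ud.grid.y0 + (j + 0.5) * ud.grid.cell_m
            d = np.hypot(
                cx - gt.winter_centroid[0], cy - gt.winter_centroid[1]
            )
            assert d <= 2 * ud.grid.cell_m

    def test_gap_capped_bridges_are_skipped(self):
        params = BBMMParams(
            sigma1_m=2.0, sigma2_m=30.0, max_bridge_gap_h=1.0
        )
        x = np.array([0.0, 100.0, 200.0]) + ORIGIN[0]
        y = np.full(3, ORIGIN[1])
        t = np.array([0.0, 1800.0, 90000.0])
        ud = compute_ud(x, y, t, params)
        assert ud.total_mass() == pytest.approx(1.0, abs=1e-6)
        with pytest.raises(ValueError, match="gap"):
            compute_ud(x[1:], y[1:], t[1:], params)

    def test_doubling_padding_leaves_isopleth_areas_unchanged(self):
        rng = np.random.default_rng(7)
        n = 50
        x = ORIGIN[0] + np.cumsum(rng.normal(0, 100, n))
        y = ORIGIN[1] + np.cumsum(rng.normal(0, 100, n))
        t = np.arange(n) * 7200.0
        params = BBMMParams(sigma1_m=2.0, sigma2_m=30.0)
        cfg = BBMMConfig()
        grid1 = GridSpec.covering(
            x.min(), y.min(), x.max(), y.max(), 50.0, 2000.0
        )
        grid2 = GridSpec.covering(
            x.min(), y.min(), x.max(), y.max(), 50.0, 4000.0
        )
        a1 = isopleth(compute_ud(x, y, t, params, cfg, grid1), 0.95).area_ha
        a2 = isopleth(compute_ud(x, y, t, params, cfg, grid2), 0.95).area_ha
        assert abs(a1 - a2) / a1 < 0.005


class TestSigma1:
    def test_recovery_on_brownian_tracks(self):
        errs = []
        for seed in range(1, 21):
            x, y, t = simulate_brownian_track(seed, 1000, sigma1=1.5)
            est, _ = estimate_sigma1(x, y, t, sigma2_m=30.0)
            errs.append(abs(est - 1.5) / 1.5)
        assert np.median(errs) <= 0.15

    def test_degenerate_track_returns_lower_bound(self):
        x = np.full(11, ORIGIN[0])
        y = np.full(11, ORIGIN[1])
        t = np.arange(11) * 3600.0
        est, profile = estimate_sigma1(x, y, t, bounds=(1e-3, 50.0))
        assert est == 1e-3
        # with zero displacements the likelihood is maximal at the bound
        assert int(np.argmax(profile[:, 1])) == 0

    def test_translation_invariance(self):
        x, y, t = simulate_brownian_track(4, 200, sigma1=1.0)
        e1, _ = estimate_sigma1(x, y, t)
        e2, _ = estimate_sigma1(x + 1e5, y - 2e5, t)
        assert e1 == pytest.approx(e2, rel=1e-9)

    def test_requires_increasing_timestamps(self):
        x, y, t = simulate_brownian_track(4, 10)
        with pytest.raises(ValueError):
            estimate_sigma1(x, y, t[::-1])


class TestIsopleth:
    def _uniform_ud(self, n_cells=100):
        grid = GridSpec(x0=0.0, y0=0.0, cell_m=50.0, nx=10, ny=10)
        mass = np.full((10, 10), 1.0 / n_cells)
        params = BBMMParams(sigma1_m=1.0)
        return UDSurface(grid=grid, mass=mass, params=params, n_fixes=2)

    def test_uniform_closed_forms(self):
        ud = self._uniform_ud()
        r95 = isopleth(ud, 0.95)
        assert len(r95.cells) == 95
        assert r95.area_ha == pytest.approx(23.75)
        r10 = isopleth(ud, 0.10)
        assert len(r10.cells) == 10
        assert r10.area_ha == pytest.approx(2.5)

    @given(seed=st.integers(0, 10_000))
    def test_nesting_and_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        mass = rng.random((8, 12))
        mass /= mass.sum()
        ud = UDSurface(
            grid=GridSpec(0.0, 0.0, 50.0, 12, 8),
            mass=mass,
            params=BBMMParams(sigma1_m=1.0),
            n_fixes=2,
        )
        inner = isopleth(ud, 0.5)
        outer = isopleth(ud, 0.95)
        assert inner.cells <= outer.cells
        assert inner.area_ha <= outer.area_ha

    def test_invalid_quantile(self):
        with pytest.raises(ValueError):
            isopleth(self._uniform_ud(), 1.0)
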