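"""Shared fixtures: deterministic hypothesis profile, the brute-force
Brownian bridge oracle, and the session-wide simulated recovery suite."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ovitrack.bbmm_core import BBMMParams, GridSpec
from ovitrack.strategy_report import analyze_cohort
from ovitrack.synthetic_data import (
    STRATEGIES,
    config_for_strategy,
    dem_for_track,
    simulate_track,
)
from ovitrack.telemetry_io import Track

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def oracle_bridge_density(
    za,
    zb,
    gap_s: float,
    params: BBMMParams,
    grid: GridSpec,
    n_alpha: int = 1000,
    sub: int = 40,
) -> np.ndarray:
    """Brute-force bridge density: dense midpoint quadrature over the
    bridge time fraction and over sub-cell space (plain Gaussian density
    sampling, no closed-form cell integrals)."""
    out = np.zeros((grid.ny, grid.nx))
    c = grid.cell_m
    offs = (np.arange(sub) + 0.5) / sub * c
    xs = grid.x0 + np.add.outer(np.arange(grid.nx) * c, offs).ravel()
    ys = grid.y0 + np.add.outer(np.arange(grid.ny) * c, offs).ravel()
    for k in range(n_alpha):
        a = (k + 0.5) / n_alpha
        var = (
            gap_s * a * (1 - a) * params.sigma1_m**2
            + ((1 - a) ** 2 + a**2) * params.sigma2_m**2
        )
        mux = (1 - a) * za[0] + a * zb[0]
        muy = (1 - a) * za[1] + a * zb[1]
        gx = np.exp(-((xs - mux) ** 2) / (2 * var)) / np.sqrt(2 * np.pi * var)
        gy = np.exp(-((ys - muy) ** 2) / (2 * var)) / np.sqrt(2 * np.pi * var)
        gxc = gx.reshape(grid.nx, sub).sum(axis=1) * c / sub
        gyc = gy.reshape(grid.ny, sub).sum(axis=1) * c / sub
        out += np.outer(gyc, gxc) / n_alpha
    return out


@pytest.fixture(scope="session")
def bridge_oracle():
    return oracle_bridge_density


def make_track(
    xy_km: list[tuple[float, float]],
    interval_h: float = 1.0,
    start: str = "2019-06-01",
    animal_id: str = "T",
    origin=(400_000.0, 6_500_000.0),
) -> Track:
    """Small hand-built track from km offsets relative to an origin."""
    xy = np.asarray(xy_km, dtype=float) * 1000.0 + np.asarray(origin)
    t = pd.date_range(start, periods=len(xy), freq=pd.Timedelta(hours=interval_h))
    fixes = pd.DataFrame(
        {
            "t": t,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "lon": np.nan,
            "lat": np.nan,
            "n_sats": 8.0,
            "elev_m": np.nan,
        }
    )
    return Track(animal_id=animal_id, fixes=fixes, crs="metric")


@pytest.fixture(scope="session")
def track_factory():
    return make_track


@pytest.fixture(scope="session")
def recovery_suite():
    """Sixty simulated animals (ten per strategy archetype, seeds 1-60)
    pushed through the full classification chain, each with the DEM its
    scenario prescribes; migrants also get corridors and stopovers."""
    out = []
    for k in range(1, 61):
        strategy = STRATEGIES[(k - 1) // 10]
        cfg = config_for_strategy(strategy, k)
        track, gt = simulate_track(cfg)
        dem = dem_for_track(track, cfg)
        cohort = analyze_cohort([track], dem=dem, with_corridors=True)
        out.append((cfg, gt, cohort.results[track.animal_id]))
    return out
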