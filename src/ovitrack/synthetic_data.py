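"""Seeded GPS-track, band and DEM simulator with ground-truth labels.

The generator emulates collar data from small bands of mountain sheep:
1-2 h fix schedules over most of a year, ~30 m location error, shared
band-level winter/summer centroids, migration legs along waypoint routes
with optional multi-day stopovers, vacillating mid-summer returns, and
elevation profiles produced by routing the track across a synthetic DEM
(flat plain, planar ramp, or a Gaussian ridge).

Movement model: an *anchor path* a(t) encodes the behavioural schedule —
constant at the seasonal centroid during residence, moving at constant
speed along the route polyline during migration legs, stationary at
stopover or vacillation dwells — and the realised position is
``a(t) + u(t) + e`` where ``u`` is a first-order autoregressive
(Ornstein-Uhlenbeck-like) jitter whose stationary SD is segment-specific
(loose on seasonal ranges, tight on the move) and ``e`` is independent
Gaussian observation noise.  Everything is deterministic given the seed.

Six strategy archetypes are built in: long-distance migrant (LDM,
centroids ~30 km apart), short-distance migrant (SDM, ~10 km),
vacillating migrant (VAC, ~12 km with three summer returns), traditional
altitudinal migrant (TRAD_ALT, geographically resident but wintering
~300 m below its summer range on a ramp), abbreviated altitudinal
migrant (ABR_ALT, high winter and summer ranges on a ridge crest with
spring and fall excursions into the valley), and RESIDENT.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

from .raster import DemRaster
from .telemetry_io import Track

STRATEGIES = ("LDM", "SDM", "VAC", "TRAD_ALT", "ABR_ALT", "RESIDENT")

_ORIGIN = (450_000.0, 6_550_000.0)  # nominal UTM-like plane


@dataclass
class SimConfig:
    """Scenario parameters for one simulated animal."""

    strategy: str = "LDM"
    seed: int = 0
    animal_id: str | None = None
    fix_interval_h: float = 2.0
    start: date = date(2019, 3, 1)
    end: date = date(2019, 12, 31)
    winter_centroid: tuple[float, float] = _ORIGIN
    summer_centroid: tuple[float, float] | None = None
    separation_m: float | None = None
    route_waypoints: list[tuple[float, float]] | None = None
    dogleg_m: float = 1500.0
    n_stopovers_spring: int = 1
    n_stopovers_fall: int = 2
    stopover_dwell_h: float = 36.0
    n_vacillations: int = 0
    vacillation_dwell_h: float = 24.0
    vacillation_travel_h: float = 8.0
    vacillation_sd_m: float = 200.0
    # median spring/fall timing and duration of the study population
    spring_depart: date = date(2019, 6, 12)
    spring_arrive: date = date(2019, 6, 19)
    fall_depart: date = date(2019, 9, 1)
    fall_arrive: date = date(2019, 9, 13)
    residence_sd_m: float = 500.0
    residence_tau_h: float = 24.0
    route_jitter_sd_m: float = 100.0
    stopover_sd_m: float = 80.0
    jitter_tau_h: float = 6.0
    loc_error_sd_m: float = 30.0
    elevation_profile: str = "flat"   # flat | traditional | abbreviated
    dem_kind: str = "flat"            # flat | ramp | ridge
    dip_offset_m: float = 2500.0      # valley excursion distance (ABR)
    abr_spring_dip: tuple[date, date] = (date(2019, 4, 15), date(2019, 5, 3))
    abr_summer_arrive: date = date(2019, 6, 10)
    abr_fall_descend: date = date(2019, 9, 15)
    abr_fall_dip: tuple[date, date] = (date(2019, 9, 22), date(2019, 10, 10))
    abr_winter_return: date = date(2019, 10, 13)
    dropout_frac: float = 0.0
    n_teleport_spikes: int = 0
    teleport_offset_m: float = 80_000.0
    n_low_sat: int = 0
    crs: str = "metric"

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "VAC" and self.n_vacillations < 2:
            raise ValueError("vacillating strategy requires >= 2 returns")
        if self.strategy != "VAC" and self.n_vacillations:
            raise ValueError("only the vacillating strategy plants returns")


@dataclass
class GroundTruth:
    """Truth emitted alongside every simulated track; never consumed by
    the analysis pipeline."""

    animal_id: str
    strategy: str
    winter_centroid: tuple[float, float]
    summer_centroid: tuple[float, float]
    spring_depart: date | None = None
    spring_arrive: date | None = None
    fall_depart: date | None = None
    fall_arrive: date | None = None
    n_vacillations: int = 0
    stopover_centers_spring: list[tuple[float, float]] = field(
        default_factory=list
    )
    stopover_centers_fall: list[tuple[float, float]] = field(
        default_factory=list
    )
    corrupted_times: list[datetime] = field(default_factory=list)
    band_id: int | None = None


_SEPARATIONS = {
    "LDM": 30_000.0,
    "SDM": 10_000.0,
    "VAC": 12_000.0,
    "TRAD_ALT": 1_600.0,
    "ABR_ALT": 1_000.0,
    "RESIDENT": 0.0,
}


def config_for_strategy(strategy: str, seed: int, **overrides) -> SimConfig:
    """Archetype scenario for one of the six strategies."""
    kw: dict = {"strategy": strategy, "seed": seed}
    kw["separation_m"] = _SEPARATIONS[strategy]
    if strategy == "VAC":
        kw["n_vacillations"] = 3
    if strategy in ("TRAD_ALT", "ABR_ALT", "RESIDENT"):
        kw["n_stopovers_spring"] = kw["n_stopovers_fall"] = 0
        kw["dogleg_m"] = 0.0
    if strategy == "TRAD_ALT":
        kw["elevation_profile"] = "traditional"
        kw["dem_kind"] = "ramp"
    elif strategy == "ABR_ALT":
        kw["elevation_profile"] = "abbreviated"
        kw["dem_kind"] = "ridge"
    kw.update(overrides)
    return SimConfig(**kw)


# ---------------------------------------------------------------------------
# DEM construction

RIDGE_BASE_M = 1400.0
RIDGE_AMP_M = 330.0
RIDGE_WIDTH_M = 900.0
RAMP_SLOPE = 0.25
FLAT_ELEV_M = 1500.0


def make_dem(
    kind: str,
    extent: tuple[float, float, float, float],
    cell_m: float = 20.0,
    *,
    ridge_y: float | None = None,
    ramp_zero: tuple[float, float] | None = None,
    crs: str = "metric",
) -> DemRaster:
    """Synthetic DEM over ``extent`` = (xmin, ymin, xmax, ymax).

    flat: constant 1500 m; ramp: elevation rises linearly in x at 25%
    grade through ``ramp_zero`` = (x, elevation-there); ridge: Gaussian
    crest along the horizontal line y = ridge_y.
    """
    xmin, ymin, xmax, ymax = extent
    x0 = np.floor(xmin / cell_m) * cell_m
    y0 = np.floor(ymin / cell_m) * cell_m
    nx = int(np.ceil((xmax - x0) / cell_m))
    ny = int(np.ceil((ymax - y0) / cell_m))
    xc = x0 + (np.arange(nx) + 0.5) * cell_m
    yc = y0 + (np.arange(ny) + 0.5) * cell_m
    if kind == "flat":
        values = np.full((ny, nx), FLAT_ELEV_M)
    elif kind == "ramp":
        zx, ze = ramp_zero if ramp_zero else (x0, 1200.0)
        values = np.broadcast_to(
            ze + RAMP_SLOPE * (xc - zx), (ny, nx)
        ).copy()
    elif kind == "ridge":
        yr = ridge_y if ridge_y is not None else 0.5 * (ymin + ymax)
        prof = RIDGE_BASE_M + RIDGE_AMP_M * np.exp(
            -((yc - yr) ** 2) / (2 * RIDGE_WIDTH_M**2)
        )
        values = np.tile(prof[:, None], (1, nx))
    else:
        raise ValueError(f"unknown DEM kind {kind!r}")
    # ASCII-grid row order is north to south
    return DemRaster(
        x0=float(x0), y0=float(y0), cell_m=cell_m,
        values=values[::-1], crs=crs,
    )


def dem_for_track(track: Track, cfg: SimConfig, margin_m: float = 2000.0) -> DemRaster:
    """DEM of the scenario's kind covering the track with a margin."""
    x = track.fixes["x"]
    y = track.fixes["y"]
    extent = (
        float(x.min()) - margin_m,
        float(y.min()) - margin_m,
        float(x.max()) + margin_m,
        float(y.max()) + margin_m,
    )
    kw = {}
    if cfg.dem_kind == "ridge":
        kw["ridge_y"] = cfg.winter_centroid[1]
    elif cfg.dem_kind == "ramp":
        kw["ramp_zero"] = (cfg.winter_centroid[0], 1450.0)
    return make_dem(cfg.dem_kind, extent, cell_m=20.0, crs=track.crs, **kw)


# ---------------------------------------------------------------------------
# anchor-path schedule

def _polyline_cum(pts: np.ndarray) -> np.ndarray:
    seg = np.hypot(*np.diff(pts, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _point_at(pts: np.ndarray, cum: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Positions at arc lengths s along the polyline."""
    s = np.clip(s, 0.0, cum[-1])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(cum) - 2)
    seg_len = cum[idx + 1] - cum[idx]
    f = np.where(seg_len > 0, (s - cum[idx]) / np.maximum(seg_len, 1e-12), 0.0)
    return pts[idx] + f[:, None] * (pts[idx + 1] - pts[idx])


@dataclass
class _Hold:
    t0: pd.Timestamp
    t1: pd.Timestamp
    point: tuple[float, float]
    sd: float


@dataclass
class _Move:
    t0: pd.Timestamp
    t1: pd.Timestamp
    pts: np.ndarray
    sd: float


def _route_with_stopovers(
    a: tuple[float, float],
    b: tuple[float, float],
    dogleg_m: float,
    fractions: list[float],
) -> tuple[np.ndarray, list[tuple[float, float]], list[float]]:
    """Route polyline a->b with a mild perpendicular dogleg; returns the
    polyline, the stopover points at the given arc-length fractions, and
    their fractions (sorted)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = b - a
    norm = np.hypot(*d)
    perp = (
        np.array([-d[1], d[0]]) / norm if norm > 0 else np.array([0.0, 1.0])
    )
    pts = np.array([a, a + 0.5 * d + dogleg_m * perp, b])
    cum = _polyline_cum(pts)
    fractions = sorted(fractions)
    stops = [
        tuple(_point_at(pts, cum, np.array([f * cum[-1]]))[0])
        for f in fractions
    ]
    return pts, stops, fractions


def _sub_polyline(pts: np.ndarray, cum: np.ndarray, s0: float, s1: float) -> np.ndarray:
    """Portion of the polyline between arc lengths s0 and s1."""
    p0 = _point_at(pts, cum, np.array([s0]))[0]
    p1 = _point_at(pts, cum, np.array([s1]))[0]
    interior = pts[(cum > s0) & (cum < s1)]
    return np.vstack([p0, interior, p1])


def _leg_segments(
    t0: pd.Timestamp,
    t1: pd.Timestamp,
    pts: np.ndarray,
    stop_fractions: list[float],
    stops: list[tuple[float, float]],
    dwell_h: float,
    move_sd: float,
    stop_sd: float,
) -> list:
    """Split one migration leg into alternating move/hold segments with
    equal travel speed on every moving stretch."""
    total_h = (t1 - t0).total_seconds() / 3600.0
    dwell_total = dwell_h * len(stops)
    if dwell_total >= total_h:
        raise ValueError("stopover dwells exceed the migration leg duration")
    cum = _polyline_cum(pts)
    move_h = total_h - dwell_total
    segs = []
    prev_f = 0.0
    t = t0
    for f, stop in zip(stop_fractions, stops):
        mh = (f - prev_f) * move_h
        te = t + pd.Timedelta(hours=mh)
        stretch = _sub_polyline(pts, cum, prev_f * cum[-1], f * cum[-1])
        segs.append(_Move(t, te, stretch, move_sd))
        segs.append(_Hold(te, te + pd.Timedelta(hours=dwell_h), stop, stop_sd))
        t = te + pd.Timedelta(hours=dwell_h)
        prev_f = f
    stretch = _sub_polyline(pts, cum, prev_f * cum[-1], cum[-1])
    segs.append(_Move(t, t1, stretch, move_sd))
    return segs


def _build_schedule(cfg: SimConfig, gt: GroundTruth) -> list:
    wc = cfg.winter_centroid
    sc = gt.summer_centroid
    ts = lambda d: pd.Timestamp(d)  # noqa: E731
    start, end = ts(cfg.start), ts(cfg.end) + pd.Timedelta(hours=23)
    segs: list = []

    if cfg.strategy == "RESIDENT":
        segs.append(_Hold(start, end, wc, cfg.residence_sd_m))
        return segs

    if cfg.strategy == "ABR_ALT":
        # high crest residences with spring/fall valley excursions
        off = np.array([0.0, -cfg.dip_offset_m])
        sdip = tuple(np.asarray(wc) + np.array([500.0, 0.0]) + off)
        fdip = tuple(np.asarray(sc) + np.array([500.0, 0.0]) + off)
        d0, d1 = ts(cfg.abr_spring_dip[0]), ts(cfg.abr_spring_dip[1])
        f0, f1 = ts(cfg.abr_fall_dip[0]), ts(cfg.abr_fall_dip[1])
        segs += [
            _Hold(start, d0, wc, cfg.residence_sd_m),
            _Move(d0, d0 + pd.Timedelta(days=1), np.array([wc, sdip]),
                  cfg.route_jitter_sd_m),
            _Hold(d0 + pd.Timedelta(days=1), d1, sdip, 300.0),
            _Move(d1, ts(cfg.abr_summer_arrive), np.array([sdip, sc]),
                  cfg.route_jitter_sd_m),
            _Hold(ts(cfg.abr_summer_arrive), ts(cfg.abr_fall_descend), sc,
                  cfg.residence_sd_m),
            _Move(ts(cfg.abr_fall_descend), f0, np.array([sc, fdip]),
                  cfg.route_jitter_sd_m),
            _Hold(f0, f1, fdip, 300.0),
            _Move(f1, ts(cfg.abr_winter_return), np.array([fdip, wc]),
                  cfg.route_jitter_sd_m),
            _Hold(ts(cfg.abr_winter_return), end, wc, cfg.residence_sd_m),
        ]
        return segs

    # geographic schedule (LDM/SDM/VAC/TRAD_ALT)
    sp0, sp1 = ts(cfg.spring_depart), ts(cfg.spring_arrive)
    fa0, fa1 = ts(cfg.fall_depart), ts(cfg.fall_arrive)
    if not (start < sp0 < sp1 < fa0 < fa1 < end):
        raise ValueError("infeasible migration schedule")

    n_sp = cfg.n_stopovers_spring
    n_fa = cfg.n_stopovers_fall
    sp_fracs = [(i + 1) / (n_sp + 1) for i in range(n_sp)]
    fa_fracs = [(i + 1) / (n_fa + 1) for i in range(n_fa)]
    pts, sp_stops, sp_fracs = _route_with_stopovers(
        wc, sc, cfg.dogleg_m, sp_fracs
    )
    back = pts[::-1].copy()
    _, fa_stops, fa_fracs = _route_with_stopovers(
        sc, wc, -cfg.dogleg_m, fa_fracs
    )
    gt.stopover_centers_spring = sp_stops
    gt.stopover_centers_fall = fa_stops

    segs.append(_Hold(start, sp0, wc, cfg.residence_sd_m))
    segs += _leg_segments(
        sp0, sp1, pts, sp_fracs, sp_stops, cfg.stopover_dwell_h,
        cfg.route_jitter_sd_m, cfg.stopover_sd_m,
    )

    # summer residence, with optional vacillating returns
    t = sp1
    if cfg.n_vacillations:
        for k in range(cfg.n_vacillations):
            r0 = sp1 + pd.Timedelta(days=10 + 12 * k)
            travel = pd.Timedelta(hours=cfg.vacillation_travel_h)
            dwell = pd.Timedelta(hours=cfg.vacillation_dwell_h)
            segs.append(_Hold(t, r0, sc, cfg.residence_sd_m))
            segs.append(_Move(r0, r0 + travel, np.array([sc, wc]),
                              cfg.route_jitter_sd_m))
            segs.append(_Hold(r0 + travel, r0 + travel + dwell, wc,
                              cfg.vacillation_sd_m))
            segs.append(_Move(r0 + travel + dwell, r0 + 2 * travel + dwell,
                              np.array([wc, sc]), cfg.route_jitter_sd_m))
            t = r0 + 2 * travel + dwell
    segs.append(_Hold(t, fa0, sc, cfg.residence_sd_m))

    segs += _leg_segments(
        fa0, fa1, back, fa_fracs, fa_stops, cfg.stopover_dwell_h,
        cfg.route_jitter_sd_m, cfg.stopover_sd_m,
    )
    segs.append(_Hold(fa1, end, wc, cfg.residence_sd_m))
    return segs


def _anchor_path(
    segs: list, times: pd.DatetimeIndex
) -> tuple[np.ndarray, np.ndarray]:
    """Anchor positions and target jitter SDs at the fix times."""
    for a, b in zip(segs, segs[1:]):
        if a.t1 > b.t0:
            raise ValueError("schedule segments overlap")
    pos = np.zeros((len(times), 2))
    sd = np.zeros(len(times))
    tns = times.asi8
    for seg in segs:
        m = (tns >= seg.t0.value) & (tns <= seg.t1.value)
        if not m.any():
            continue
        if isinstance(seg, _Hold):
            pos[m] = np.asarray(seg.point)
        else:
            cum = _polyline_cum(seg.pts)
            frac = (tns[m] - seg.t0.value) / max(
                seg.t1.value - seg.t0.value, 1
            )
            pos[m] = _point_at(seg.pts, cum, frac * cum[-1])
        sd[m] = seg.sd
    return pos, sd


def _true_path(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[pd.DatetimeIndex, np.ndarray, GroundTruth]:
    """Noise-free realised path (anchor + behavioural jitter) plus the
    fix schedule and ground truth."""
    animal_id = cfg.animal_id or f"sim{cfg.seed:04d}"
    sep = (
        cfg.separation_m
        if cfg.separation_m is not None
        else _SEPARATIONS[cfg.strategy]
    )
    if cfg.summer_centroid is not None:
        sc = cfg.summer_centroid
    else:
        sc = (cfg.winter_centroid[0] + sep, cfg.winter_centroid[1])

    geographic = cfg.strategy in ("LDM", "SDM", "VAC")
    gt = GroundTruth(
        animal_id=animal_id,
        strategy=cfg.strategy,
        winter_centroid=cfg.winter_centroid,
        summer_centroid=sc,
        spring_depart=cfg.spring_depart if geographic else None,
        spring_arrive=cfg.spring_arrive if geographic else None,
        fall_depart=cfg.fall_depart if geographic else None,
        fall_arrive=cfg.fall_arrive if geographic else None,
        n_vacillations=cfg.n_vacillations,
    )

    times = pd.date_range(
        pd.Timestamp(cfg.start),
        pd.Timestamp(cfg.end) + pd.Timedelta(hours=23),
        freq=pd.Timedelta(hours=cfg.fix_interval_h),
    )
    segs = _build_schedule(cfg, gt)
    anchor, sd_target = _anchor_path(segs, times)

    # AR(1) jitter with segment-specific stationary SD
    dt_h = cfg.fix_interval_h
    phi = np.exp(-dt_h / cfg.jitter_tau_h)
    phi_res = np.exp(-dt_h / cfg.residence_tau_h)
    u = np.zeros((len(times), 2))
    innov = rng.standard_normal((len(times), 2))
    u[0] = sd_target[0] * innov[0]
    for k in range(1, len(times)):
        p = phi_res if sd_target[k] >= 300.0 else phi
        s = sd_target[k] * np.sqrt(1 - p**2)
        u[k] = p * u[k - 1] + s * innov[k]
    return times, anchor + u, gt


def simulate_track(cfg: SimConfig) -> tuple[Track, GroundTruth]:
    """Generate one collar track and its ground truth (seeded)."""
    rng = np.random.default_rng(cfg.seed)
    times, path, gt = _true_path(cfg, rng)
    xy = path + cfg.loc_error_sd_m * rng.standard_normal((len(times), 2))
    animal_id = gt.animal_id

    keep = np.ones(len(times), dtype=bool)
    if cfg.dropout_frac > 0:
        keep = rng.random(len(times)) >= cfg.dropout_frac
        keep[0] = keep[-1] = True

    if cfg.n_teleport_spikes:
        idx_pool = np.flatnonzero(keep)[100:-5:3]
        spikes = rng.choice(
            idx_pool, size=cfg.n_teleport_spikes, replace=False
        )
        theta = rng.uniform(0, 2 * np.pi, size=cfg.n_teleport_spikes)
        xy[spikes, 0] += cfg.teleport_offset_m * np.cos(theta)
        xy[spikes, 1] += cfg.teleport_offset_m * np.sin(theta)
        gt.corrupted_times = [times[i].to_pydatetime() for i in spikes]

    n_sats = rng.integers(5, 13, size=len(times)).astype(float)
    if cfg.n_low_sat:
        pool = np.flatnonzero(keep)[90:-5]
        low = rng.choice(pool, size=cfg.n_low_sat, replace=False)
        n_sats[low] = 2.0

    fixes = pd.DataFrame(
        {
            "t": times[keep],
            "x": xy[keep, 0],
            "y": xy[keep, 1],
            "lon": np.nan,
            "lat": np.nan,
            "n_sats": n_sats[keep],
            "elev_m": np.nan,
        }
    ).reset_index(drop=True)
    track = Track(
        animal_id=animal_id,
        fixes=fixes,
        crs=cfg.crs,
        capture_date=cfg.start,
        nominal_interval_h=cfg.fix_interval_h,
    )
    return track, gt


def derive_seed(master_seed: int, k: int) -> int:
    return int((master_seed * 1_000_003 + 7919 * (k + 1)) % (2**31 - 1))


def simulate_band(
    n_animals: int,
    cfg: SimConfig,
    spread_m: float = 100.0,
    band_id: int | None = None,
) -> list[tuple[Track, GroundTruth]]:
    """Simulate a gregarious band.

    All members share the band's realised movement path (sheep bands move
    as one unit), and each member adds an independent positional jitter
    with stationary SD ``spread_m`` plus its own observation noise.
    Per-member seeds are derived reproducibly from the master seed.
    """
    if n_animals < 1:
        raise ValueError("a band needs at least one animal")
    band_rng = np.random.default_rng(derive_seed(cfg.seed, 0))
    times, path, gt0 = _true_path(cfg, band_rng)
    phi = np.exp(-cfg.fix_interval_h / cfg.jitter_tau_h)
    out = []
    for k in range(n_animals):
        seed_k = derive_seed(cfg.seed, k)
        rng = np.random.default_rng(seed_k)
        u = np.zeros((len(times), 2))
        innov = rng.standard_normal((len(times), 2))
        u[0] = spread_m * innov[0]
        for i in range(1, len(times)):
            u[i] = phi * u[i - 1] + spread_m * np.sqrt(1 - phi**2) * innov[i]
        xy = path + u + cfg.loc_error_sd_m * rng.standard_normal(
            (len(times), 2)
        )
        animal_id = f"b{cfg.seed}a{k}"
        fixes = pd.DataFrame(
            {
                "t": times,
                "x": xy[:, 0],
                "y": xy[:, 1],
                "lon": np.nan,
                "lat": np.nan,
                "n_sats": rng.integers(5, 13, size=len(times)).astype(float),
                "elev_m": np.nan,
            }
        )
        track = Track(
            animal_id=animal_id,
            fixes=fixes,
            crs=cfg.crs,
            capture_date=cfg.start,
            nominal_interval_h=cfg.fix_interval_h,
        )
        gt = GroundTruth(
            **{
                **dataclasses.asdict(gt0),
                "animal_id": animal_id,
                "band_id": band_id if band_id is not None else cfg.seed,
            }
        )
        out.append((track, gt))
    return out


def simulate_brownian_track(
    seed: int,
    n_fixes: int = 1000,
    interval_h: float = 2.0,
    sigma1: float = 1.0,
    loc_error_sd_m: float = 30.0,
    origin: tuple[float, float] = _ORIGIN,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pure Brownian-motion fix series (x, y, t_seconds) with observation
    noise, for motion-variance estimator calibration.  ``sigma1`` is in
    m/sqrt(s): each step has variance sigma1^2 * dt per axis."""
    rng = np.random.default_rng(seed)
    dt_s = interval_h * 3600.0
    steps = sigma1 * np.sqrt(dt_s) * rng.standard_normal((n_fixes - 1, 2))
    path = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)]) + np.asarray(
        origin
    )
    obs = path + loc_error_sd_m * rng.standard_normal((n_fixes, 2))
    t = np.arange(n_fixes) * dt_s
    return obs[:, 0], obs[:, 1], t
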