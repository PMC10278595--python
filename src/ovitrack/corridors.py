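"""Migration corridors, route distances and stopover sites.

A corridor is the Brownian bridge UD over the fixes of one migration leg
(padded by 24 h on each side, so the bridges into and out of the
seasonal ranges are anchored).  Stopover sites are the connected
components of the corridor UD's top-10% isopleth, screened against the
animal's seasonal ranges, filtered by occupancy time, and merged when
their nearest cell edges are closer than 300 m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .bbmm_core import (
    BBMMConfig,
    GridSpec,
    RangePolygon,
    UDSurface,
    isopleth,
)
from .config import CorridorConfig
from .displacement import MigrationEvent
from .ranges import segment_ud
from .telemetry_io import Track

log = logging.getLogger(__name__)


@dataclass
class Corridor:
    animal_id: str
    season: str  # "spring" | "fall"
    ud: UDSurface
    polygon95: RangePolygon
    route_distance_km: float


@dataclass
class StopoverSite:
    site_id: str
    cells: frozenset
    cell_m: float
    occupancy: dict[str, float] = field(default_factory=dict)  # id -> hours

    @property
    def area_ha(self) -> float:
        return len(self.cells) * self.cell_m**2 / 1e4

    @property
    def centroid(self) -> tuple[float, float]:
        arr = np.array(sorted(self.cells), dtype=float)
        c = self.cell_m
        return (
            float((arr[:, 0].mean() + 0.5) * c),
            float((arr[:, 1].mean() + 0.5) * c),
        )

    def as_range(self) -> RangePolygon:
        return RangePolygon(cells=self.cells, cell_m=self.cell_m, q=0.10)


def _season_window(event: MigrationEvent, season: str, pad_h: float):
    if season == "spring":
        start, end = event.spring_start, event.spring_end
    elif season == "fall":
        if event.fall_end is None:
            raise ValueError("fall migration unconfirmed (truncated series)")
        start, end = event.fall_start, event.fall_end
    else:
        raise ValueError(f"unknown season {season!r}")
    t0 = pd.Timestamp(start) - pd.Timedelta(hours=pad_h)
    t1 = pd.Timestamp(end) + pd.Timedelta(days=1) + pd.Timedelta(hours=pad_h)
    return t0, t1


def route_distance(
    track: Track, event: MigrationEvent, season: str
) -> float:
    """Cumulative Euclidean step length (km) over the fixes strictly
    inside the migration dates (no padding)."""
    transit = (
        event.spring_transit if season == "spring" else event.fall_transit
    )
    if transit is not None:
        f = track.fixes
        seg = f[(f["t"] >= transit[0]) & (f["t"] <= transit[1])]
    else:
        if season == "spring":
            start, end = event.spring_start, event.spring_end
        else:
            if event.fall_end is None:
                return float("nan")
            start, end = event.fall_start, event.fall_end
        seg = track.between(start, end)
    if len(seg) < 2:
        log.warning(
            "track %s: %s migration window has <2 fixes, distance 0",
            track.animal_id,
            season,
        )
        return 0.0
    dx = np.diff(seg["x"].to_numpy())
    dy = np.diff(seg["y"].to_numpy())
    return float(np.hypot(dx, dy).sum() / 1000.0)


def corridor_ud(
    track: Track,
    event: MigrationEvent,
    season: str,
    bbmm_cfg: BBMMConfig | None = None,
    corridor_cfg: CorridorConfig | None = None,
) -> Corridor:
    """Corridor UD with its 95% polygon and route distance."""
    bbmm_cfg = bbmm_cfg or BBMMConfig()
    corridor_cfg = corridor_cfg or CorridorConfig()
    t0, t1 = _season_window(event, season, corridor_cfg.pad_h)
    seg = track.fixes[(track.fixes["t"] >= t0) & (track.fixes["t"] <= t1)]
    if len(seg) < 4:
        raise ValueError(
            f"track {track.animal_id}: fewer than 4 fixes in the padded "
            f"{season} migration window"
        )
    ud = segment_ud(seg, bbmm_cfg)
    poly = isopleth(ud, 0.95, animal_id=track.animal_id, season=season)
    return Corridor(
        animal_id=track.animal_id,
        season=season,
        ud=ud,
        polygon95=poly,
        route_distance_km=route_distance(track, event, season),
    )


def _components(cells: frozenset, cell_m: float) -> list[frozenset]:
    """Split a cell set into 8-connected components."""
    arr = np.array(sorted(cells))
    gx0, gy0 = arr[:, 0].min(), arr[:, 1].min()
    nx = arr[:, 0].max() - gx0 + 1
    ny = arr[:, 1].max() - gy0 + 1
    mask = np.zeros((ny, nx), dtype=bool)
    mask[arr[:, 1] - gy0, arr[:, 0] - gx0] = True
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    out = []
    for k in range(1, n + 1):
        jj, ii = np.nonzero(lab == k)
        out.append(
            frozenset(zip((ii + gx0).tolist(), (jj + gy0).tolist()))
        )
    return out


def _occupancy_hours(track: Track, cells: frozenset, cell_m: float) -> float:
    """Time attributed to a cell set: the sum of inter-fix intervals whose
    spatial midpoint falls inside it."""
    f = track.fixes
    x = f["x"].to_numpy()
    y = f["y"].to_numpy()
    t = f["t"].to_numpy().astype("datetime64[s]").astype(float)
    mx = 0.5 * (x[:-1] + x[1:])
    my = 0.5 * (y[:-1] + y[1:])
    gx = np.floor(mx / cell_m).astype(int)
    gy = np.floor(my / cell_m).astype(int)
    dt_h = np.diff(t) / 3600.0
    inside = np.fromiter(
        ((a, b) in cells for a, b in zip(gx, gy)), dtype=bool, count=len(gx)
    )
    return float(dt_h[inside].sum())


def _edge_distance(a: frozenset, b: frozenset, cell_m: float) -> float:
    """Nearest distance between the cell-edge boundaries of two sets."""
    ra = RangePolygon(cells=a, cell_m=cell_m, q=0.1)
    rb = RangePolygon(cells=b, cell_m=cell_m, q=0.1)
    return float(ra.polygon.distance(rb.polygon))


def extract_stopovers(
    corridor: Corridor,
    track: Track,
    seasonal_ranges: list[RangePolygon],
    cfg: CorridorConfig | None = None,
) -> list[StopoverSite]:
    """Stopover sites of one animal-season.

    Pipeline: top-10% isopleth of the corridor UD -> 8-connected
    components -> drop components touching the animal's summer or winter
    95% range -> drop components with under 12 h of attributed location
    data -> merge components whose cell edges are closer than 300 m
    (iterated to a fixed point; the merge graph's connected components
    make the result order-independent).
    """
    cfg = cfg or CorridorConfig()
    top = isopleth(corridor.ud, cfg.stopover_q)
    comps = _components(top.cells, top.cell_m)

    range_cells = frozenset().union(
        *[r.cells for r in seasonal_ranges if r is not None]
    ) if seasonal_ranges else frozenset()
    comps = [c for c in comps if not (c & range_cells)]

    kept = []
    for c in comps:
        hours = _occupancy_hours(track, c, top.cell_m)
        if hours >= cfg.min_occupancy_h:
            kept.append((c, hours))

    # merge near components via a proximity graph (fixed point in one
    # pass over connected components of the "closer than 300 m" relation)
    merged = _merge_near(kept, top.cell_m, cfg.merge_distance_m)
    sites = []
    for k, (cells, hours) in enumerate(merged):
        sites.append(
            StopoverSite(
                site_id=f"{corridor.animal_id}-{corridor.season}-{k}",
                cells=cells,
                cell_m=top.cell_m,
                occupancy={corridor.animal_id: hours},
            )
        )
    return sites


def _merge_near(
    comps: list[tuple[frozenset, float]],
    cell_m: float,
    merge_m: float,
) -> list[tuple[frozenset, float]]:
    if not comps:
        return []
    n = len(comps)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _edge_distance(comps[i][0], comps[j][0], cell_m) < merge_m:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        cells = frozenset().union(*[comps[i][0] for i in members])
        hours = sum(comps[i][1] for i in members)
        out.append((cells, hours))
    out.sort(key=lambda ch: sorted(ch[0])[0])
    return out


def band_corridor(member_corridors: list[Corridor]) -> UDSurface:
    """Combined band corridor: cell-wise mean of the member UDs on the
    union grid (exact, thanks to the shared lattice), renormalised."""
    if not member_corridors:
        raise ValueError("need at least one member corridor")
    cell = member_corridors[0].ud.grid.cell_m
    gx0 = min(c.ud.grid.gx0 for c in member_corridors)
    gy0 = min(c.ud.grid.gy0 for c in member_corridors)
    gx1 = max(c.ud.grid.gx0 + c.ud.grid.nx for c in member_corridors)
    gy1 = max(c.ud.grid.gy0 + c.ud.grid.ny for c in member_corridors)
    grid = GridSpec(
        x0=gx0 * cell, y0=gy0 * cell, cell_m=cell, nx=gx1 - gx0, ny=gy1 - gy0
    )
    mass = np.zeros((grid.ny, grid.nx))
    for c in member_corridors:
        g = c.ud.grid
        ox, oy = g.gx0 - gx0, g.gy0 - gy0
        mass[oy:oy + g.ny, ox:ox + g.nx] += c.ud.mass
    mass /= len(member_corridors)
    mass /= mass.sum()
    return UDSurface(
        grid=grid,
        mass=mass,
        params=member_corridors[0].ud.params,
        n_fixes=sum(c.ud.n_fixes for c in member_corridors),
    )
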