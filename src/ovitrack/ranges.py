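"""Seasonal 95% ranges, overlaps, band assignment and winter fidelity.

All range geometry lives on the shared global 50 m cell lattice, so
intersection areas and percentages are exact cell-set arithmetic.
Directional thresholds stated as "overlap > X%" are applied to the
percentage of the *smaller* range (the conservative reading), which for
the band rule equals the minimum of the two directional percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .bbmm_core import (
    BBMMConfig,
    BBMMParams,
    RangePolygon,
    compute_ud,
    estimate_sigma1,
    isopleth,
)
from .config import RangeConfig
from .displacement import SeasonWindow
from .telemetry_io import Track

log = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    area_ha: float
    pct_of_first: float
    pct_of_second: float


def fit_segment_params(
    seg: pd.DataFrame, bbmm_cfg: BBMMConfig
) -> BBMMParams:
    """Per-segment BBMM parameters: sigma1 by maximum likelihood on the
    segment's own fixes, sigma2 from config."""
    t_s = seg["t"].to_numpy().astype("datetime64[s]").astype(float)
    sigma1, _ = estimate_sigma1(
        seg["x"].to_numpy(),
        seg["y"].to_numpy(),
        t_s,
        sigma2_m=bbmm_cfg.sigma2_m,
        bounds=bbmm_cfg.sigma1_bounds,
    )
    return BBMMParams(
        sigma1_m=sigma1,
        sigma2_m=bbmm_cfg.sigma2_m,
        max_bridge_gap_h=bbmm_cfg.max_bridge_gap_h,
    )


def segment_ud(seg: pd.DataFrame, bbmm_cfg: BBMMConfig):
    params = fit_segment_params(seg, bbmm_cfg)
    t_s = seg["t"].to_numpy().astype("datetime64[s]").astype(float)
    return compute_ud(
        seg["x"].to_numpy(), seg["y"].to_numpy(), t_s, params, bbmm_cfg
    )


def seasonal_range(
    track: Track,
    window: tuple,
    season: str,
    bbmm_cfg: BBMMConfig | None = None,
    range_cfg: RangeConfig | None = None,
    year: int | None = None,
) -> RangePolygon | None:
    """95% isopleth of the Brownian bridge UD over the season window.

    Returns None (with a log flag) when the window holds fewer than the
    configured minimum days of data.
    """
    bbmm_cfg = bbmm_cfg or BBMMConfig()
    range_cfg = range_cfg or RangeConfig()
    seg = track.between(*window)
    if seg.empty or (
        (seg["t"].iloc[-1] - seg["t"].iloc[0])
        < pd.Timedelta(days=range_cfg.min_window_days)
    ):
        log.warning(
            "track %s: insufficient fixes in %s window, no range",
            track.animal_id,
            season,
        )
        return None
    ud = segment_ud(seg, bbmm_cfg)
    return isopleth(
        ud,
        range_cfg.isopleth_q,
        animal_id=track.animal_id,
        season=season,
        year=year if year is not None else seg["t"].iloc[0].year,
    )


def overlap(a: RangePolygon, b: RangePolygon) -> OverlapResult:
    """Cell-set intersection of two ranges on the shared lattice."""
    if a.cell_m != b.cell_m:
        raise ValueError("ranges are on different grids")
    inter = a.cells & b.cells
    area_ha = len(inter) * a.cell_m**2 / 1e4
    return OverlapResult(
        area_ha=area_ha,
        pct_of_first=100.0 * len(inter) / len(a.cells),
        pct_of_second=100.0 * len(inter) / len(b.cells),
    )


def overlap_of_smaller(a: RangePolygon, b: RangePolygon) -> float:
    """Shared area as a percentage of the smaller of the two ranges."""
    inter = len(a.cells & b.cells)
    return 100.0 * inter / min(len(a.cells), len(b.cells))


def is_geographic_migrant(
    summer_on_winter_pct: float, max_overlap_pct: float = 20.0
) -> bool:
    """Strict-inequality overlap rule: a migrant's summer range covers
    less than ``max_overlap_pct`` of its winter range."""
    return summer_on_winter_pct < max_overlap_pct


def co_movement_score(
    a: Track,
    b: Track,
    proximity_m: float = 500.0,
    tolerance_h: float = 1.0,
) -> float:
    """Fraction of time-matched fix pairs (nearest within tolerance)
    closer than ``proximity_m``."""
    fa = a.fixes[["t", "x", "y"]].rename(columns={"x": "xa", "y": "ya"})
    fb = b.fixes[["t", "x", "y"]].rename(columns={"x": "xb", "y": "yb"})
    merged = pd.merge_asof(
        fa.sort_values("t"),
        fb.sort_values("t"),
        on="t",
        direction="nearest",
        tolerance=pd.Timedelta(hours=tolerance_h),
    ).dropna()
    if merged.empty:
        return 0.0
    d = np.hypot(merged["xa"] - merged["xb"], merged["ya"] - merged["yb"])
    return float(np.mean(d < proximity_m))


def assign_bands(
    winter_ranges: dict[str, RangePolygon],
    tracks: dict[str, Track],
    cfg: RangeConfig | None = None,
) -> list[set[str]]:
    """Partition animals into bands: connected components of the graph
    with an edge when the winter ranges overlap more than the threshold
    (of the smaller range) and the pair frequently moves together."""
    cfg = cfg or RangeConfig()
    ids = sorted(winter_ranges)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            pct = overlap_of_smaller(winter_ranges[a], winter_ranges[b])
            if pct <= cfg.band_min_overlap_pct:
                continue
            score = co_movement_score(
                tracks[a], tracks[b], cfg.proximity_m, cfg.match_tolerance_h
            )
            if score > cfg.co_movement_frac:
                g.add_edge(a, b)
    comps = [set(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: sorted(c)[0])


def winter_fidelity(
    yearly_ranges: list[RangePolygon],
    min_overlap_pct: float = 50.0,
) -> bool:
    """Fidelity iff every consecutive-year winter-range pair overlaps
    more than the threshold (of the smaller range); an animal with three
    winters must pass both pairs."""
    if len(yearly_ranges) < 2:
        raise ValueError("fidelity needs at least two winter ranges")
    ordered = sorted(yearly_ranges, key=lambda r: (r.year or 0))
    return all(
        overlap_of_smaller(a, b) > min_overlap_pct
        for a, b in zip(ordered, ordered[1:])
    )


def winter_year(window: SeasonWindow) -> int:
    """A winter spanning December-March is labelled by the year holding
    its January."""
    start, end = window.winter
    return end.year
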