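"""Net squared displacement, migration-date detection, vacillation
counting and season-window construction.

Net squared displacement (NSD) is the squared Euclidean distance of every
fix from a fixed winter reference location.  A geographic migrant shows a
sustained NSD plateau far above its winter radius; the detector below is
a deterministic surrogate for the visual NSD-plot inspection used in
field studies, with every constant exposed in :class:`DetectorConfig`.

Detector outline (daily series = per-day median NSD, then a centred
3-day rolling median):

1. winter radius ``r_w`` = 95th percentile of sqrt(NSD) over the 30 days
   after the reference date;
2. candidate days have smoothed NSD above ``plateau_frac`` times the 95th
   percentile of the smoothed series; consecutive candidate days form
   runs, and runs shorter than ``min_run_days`` are ignored as blips;
3. the animal is a migrant iff the longest run lasts at least 30 days and
   its median displacement exceeds ``min_separation_factor * r_w``;
4. the plateau period spans the first to the last candidate run (a
   vacillating migrant's returns split the plateau into several runs, so
   anchoring dates to the longest run alone would misdate its spring
   arrival); arrival/departure dates are refined to the first/last day at
   ``arrival_frac`` of the plateau's median NSD, and the bracketing
   crossings of ``r_w^2`` give the departure from / return to the winter
   range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .config import DetectorConfig, SeasonTemplate
from .bbmm_core import RangePolygon
from .telemetry_io import Track

log = logging.getLogger(__name__)


@dataclass
class DisplacementSeries:
    """Per-fix and per-day NSD (km^2) from a winter reference point."""

    animal_id: str
    reference_date: date
    x0: float
    y0: float
    fix_t: pd.Series
    fix_nsd: np.ndarray          # km^2, aligned with fix_t
    daily: pd.Series             # per-day median NSD, daily DatetimeIndex
    smoothed: pd.Series          # centred 3-day rolling median of daily


@dataclass
class MigrationEvent:
    """Spring/fall migration dates for one animal-year."""

    animal_id: str
    spring_start: date
    spring_end: date
    fall_start: date
    fall_end: date | None
    n_vacillations: int = 0
    truncated: bool = False
    # fix-resolution transit bounds (filled by the detector when the fix
    # series is available); route distances use these so pre-departure /
    # post-arrival residence wander is not counted as travel
    spring_transit: tuple[pd.Timestamp, pd.Timestamp] | None = None
    fall_transit: tuple[pd.Timestamp, pd.Timestamp] | None = None

    def __post_init__(self) -> None:
        if not self.spring_start <= self.spring_end:
            raise ValueError("spring_start must not follow spring_end")
        if not self.spring_end < self.fall_start:
            raise ValueError("fall must follow spring")
        if self.fall_end is not None and self.fall_start > self.fall_end:
            raise ValueError("fall_start must not follow fall_end")

    @property
    def spring_duration_d(self) -> int:
        return max(1, (self.spring_end - self.spring_start).days)

    @property
    def fall_duration_d(self) -> int | None:
        if self.fall_end is None:
            return None
        return max(1, (self.fall_end - self.fall_start).days)


@dataclass
class SeasonWindow:
    """Winter and summer date intervals for one animal."""

    animal_id: str
    winter: tuple[date, date]
    summer: tuple[date, date]
    provenance: str  # "migrant-derived" | "resident-percentile"


def compute_nsd(track: Track, reference_date: date) -> DisplacementSeries:
    """NSD (km^2) of every fix from the first fix at/after the reference
    date, plus the smoothed daily series used by the detector."""
    t = track.fixes["t"]
    ref_ts = pd.Timestamp(reference_date)
    idx = np.searchsorted(t.to_numpy(), np.datetime64(ref_ts))
    if idx >= len(t) or (t.iloc[idx] - ref_ts) > pd.Timedelta(days=7):
        raise ValueError(
            f"track {track.animal_id}: no fix within 7 days of "
            f"{reference_date}"
        )
    x0 = float(track.fixes["x"].iloc[idx])
    y0 = float(track.fixes["y"].iloc[idx])
    sub = track.fixes.iloc[idx:]
    nsd = (
        (sub["x"].to_numpy() - x0) ** 2 + (sub["y"].to_numpy() - y0) ** 2
    ) / 1e6
    daily = (
        pd.Series(nsd, index=pd.DatetimeIndex(sub["t"]).normalize())
        .groupby(level=0)
        .median()
    )
    daily = daily.reindex(
        pd.date_range(daily.index[0], daily.index[-1], freq="D")
    )
    smoothed = daily.rolling(3, center=True, min_periods=1).median()
    return DisplacementSeries(
        animal_id=track.animal_id,
        reference_date=reference_date,
        x0=x0,
        y0=y0,
        fix_t=sub["t"].reset_index(drop=True),
        fix_nsd=nsd,
        daily=daily,
        smoothed=smoothed,
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs, stop exclusive."""
    out = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def detect_migration(
    series: DisplacementSeries,
    cfg: DetectorConfig | None = None,
) -> MigrationEvent | None:
    """Classify the series as migrant (returning dated events) or
    resident (returning None).  See the module docstring for the rule."""
    cfg = cfg or DetectorConfig()
    sm = series.smoothed
    if len(sm) < 90:
        raise ValueError("need at least ~3 months of daily series")

    ref_ts = pd.Timestamp(series.reference_date)
    early = series.fix_nsd[
        (series.fix_t >= ref_ts)
        & (series.fix_t < ref_ts + pd.Timedelta(days=cfg.winter_radius_days))
    ]
    if len(early) == 0:
        raise ValueError("no fixes in the winter-radius window")
    r_w_km = float(np.percentile(np.sqrt(early), cfg.winter_radius_pct))
    r_w2 = r_w_km**2

    vals = sm.to_numpy()
    finite = np.isfinite(vals)
    thr = cfg.plateau_frac * np.percentile(vals[finite], cfg.plateau_pct)
    candidate = finite & (vals > thr)
    runs = [r for r in _runs(candidate) if r[1] - r[0] >= cfg.min_run_days]
    if not runs:
        return None

    longest = max(runs, key=lambda r: r[1] - r[0])
    long_len = longest[1] - longest[0]
    plateau_disp = float(
        np.sqrt(np.nanmedian(vals[longest[0]:longest[1]]))
    )
    if long_len < cfg.min_plateau_days:
        return None
    if plateau_disp <= cfg.min_separation_factor * r_w_km:
        return None

    # plateau period spans first..last run; refine dates against its level
    first_day = runs[0][0]
    last_day = runs[-1][1] - 1
    cand_idx = np.concatenate([np.arange(a, b) for a, b in runs])
    plateau_level = float(np.nanmedian(vals[cand_idx]))
    high = finite & (vals >= cfg.arrival_frac * plateau_level)
    high_idx = np.flatnonzero(high[first_day:last_day + 1]) + first_day
    if len(high_idx) == 0:  # degenerate; fall back to run edges
        arr_i, dep_i = first_day, last_day
    else:
        arr_i, dep_i = int(high_idx[0]), int(high_idx[-1])

    days = sm.index
    spring_end = days[arr_i].date()
    below = np.flatnonzero(finite[:arr_i] & (vals[:arr_i] <= r_w2))
    spring_start = days[int(below[-1])].date() if len(below) else days[0].date()

    fall_start = days[dep_i].date()
    fall_end = None
    truncated = False
    quiet_n = cfg.return_window_days
    tail = np.flatnonzero(finite[dep_i + 1:] & (vals[dep_i + 1:] <= r_w2))
    for off in tail:
        i = dep_i + 1 + int(off)
        window = vals[i:i + quiet_n]
        fin = np.isfinite(window)
        if fin.sum() == 0:
            continue
        # confirmed return: the following month is typically in-range
        # (median below r_w^2 -- robust to occasional jitter excursions)
        if np.median(window[fin]) <= r_w2:
            fall_end = days[i].date()
            truncated = len(vals) - i < quiet_n
            break
    if fall_end is None:
        truncated = True
        log.info(
            "track %s: series ends before the fall return is confirmed",
            series.animal_id,
        )
    if fall_start <= spring_end:
        # plateau collapsed to a sliver; treat as resident
        return None
    event = MigrationEvent(
        animal_id=series.animal_id,
        spring_start=spring_start,
        spring_end=spring_end,
        fall_start=fall_start,
        fall_end=fall_end,
        truncated=truncated,
    )
    _attach_transits(
        event, series, r_w2, cfg.arrival_frac * plateau_level
    )
    return event


def _attach_transits(
    event: MigrationEvent,
    series: DisplacementSeries,
    r_w2: float,
    arrival_level: float,
) -> None:
    """Fix-resolution transit bounds: from the last in-winter fix before
    the plateau to the first fix at plateau level (spring), and the
    mirror image for fall."""
    t = series.fix_t.to_numpy()
    nsd = series.fix_nsd
    sp_hi = np.flatnonzero(
        (t <= np.datetime64(pd.Timestamp(event.spring_end) + pd.Timedelta(days=1)))
        & (nsd >= arrival_level)
    )
    if len(sp_hi):
        arr = int(sp_hi[0])
        low = np.flatnonzero((np.arange(len(t)) < arr) & (nsd <= r_w2))
        dep = int(low[-1]) if len(low) else 0
        event.spring_transit = (pd.Timestamp(t[dep]), pd.Timestamp(t[arr]))
    fa_hi = np.flatnonzero(
        (t >= np.datetime64(pd.Timestamp(event.fall_start) - pd.Timedelta(days=1)))
        & (nsd >= arrival_level)
    )
    if len(fa_hi):
        dep = int(fa_hi[-1])
        low = np.flatnonzero((np.arange(len(t)) > dep) & (nsd <= r_w2))
        if len(low):
            event.fall_transit = (
                pd.Timestamp(t[dep]),
                pd.Timestamp(t[int(low[0])]),
            )


def count_vacillations(
    track: Track,
    event: MigrationEvent,
    winter_range: RangePolygon,
    min_return_fixes: int = 6,
) -> int:
    """Number of distinct summer returns to the winter range: maximal
    intervals strictly between spring arrival and fall departure during
    which at least ``min_return_fixes`` consecutive fixes fall inside the
    winter 95% polygon."""
    t = track.fixes["t"]
    m = (t > pd.Timestamp(event.spring_end) + pd.Timedelta(days=1)) & (
        t < pd.Timestamp(event.fall_start)
    )
    sub = track.fixes.loc[m]
    if sub.empty:
        return 0
    inside = winter_range.contains_xy(
        sub["x"].to_numpy(), sub["y"].to_numpy()
    )
    return sum(
        1 for a, b in _runs(inside) if b - a >= min_return_fixes
    )


def _percentile_doy(values: list[float], pct: float) -> int:
    """Linear-interpolated percentile of day-ordinals, rounded half-up."""
    v = float(np.percentile(np.asarray(values, dtype=float), pct))
    return int(np.floor(v + 0.5))


def resident_seasons(
    events: list[MigrationEvent],
) -> dict[str, int]:
    """Percentile-based season template from migrant events.

    Returns day-of-year ordinals: summer = [P66 of spring ends, P33 of
    fall starts]; winter = [P66 of fall ends, P33 of spring starts].
    Fall-end dates that spill into the next calendar year are mapped past
    365 before taking percentiles, so a late outlier cannot wrap the
    window.  Requires at least 3 migrant events.
    """
    if len(events) < 3:
        raise ValueError(
            "need >= 3 migrant events for the percentile template; "
            "configure resident seasons manually"
        )

    def doy(d: date, late: bool = False) -> float:
        o = d.timetuple().tm_yday
        if late and o < 180:  # ran past the calendar-year boundary
            o += 365
        return float(o)

    spring_starts = [doy(e.spring_start) for e in events]
    spring_ends = [doy(e.spring_end) for e in events]
    fall_starts = [doy(e.fall_start, late=True) for e in events]
    fall_ends = [
        doy(e.fall_end, late=True) for e in events if e.fall_end is not None
    ]
    if len(fall_ends) < 3:
        raise ValueError("need >= 3 confirmed fall ends for the template")
    return {
        "summer_start": _percentile_doy(spring_ends, 66),
        "summer_end": _percentile_doy(fall_starts, 33),
        "winter_start": _percentile_doy(fall_ends, 66),
        "winter_end": _percentile_doy(spring_starts, 33),
    }


def _doy_to_date(doy: int, year: int) -> date:
    return date(year, 1, 1) + timedelta(days=int(doy) - 1)


def template_from_config(tpl: SeasonTemplate, year: int) -> dict[str, int]:
    """Config fallback template expressed as day-of-year ordinals."""
    def doy(md: tuple[int, int]) -> int:
        return date(year, md[0], md[1]).timetuple().tm_yday

    return {
        "summer_start": doy(tpl.summer_start),
        "summer_end": doy(tpl.summer_end),
        "winter_start": doy(tpl.winter_start),
        "winter_end": doy(tpl.winter_end),
    }


def season_windows_for_migrant(
    track: Track, event: MigrationEvent
) -> SeasonWindow:
    """Winter = series start to spring departure; summer = spring arrival
    to fall departure (the post-return winter is handled separately for
    fidelity analyses)."""
    return SeasonWindow(
        animal_id=track.animal_id,
        winter=(track.start.date(), event.spring_start),
        summer=(event.spring_end, event.fall_start),
        provenance="migrant-derived",
    )


def season_windows_for_resident(
    track: Track, template: dict[str, int]
) -> SeasonWindow:
    """Materialise the percentile template onto the track's span.

    The winter interval wraps the year boundary; the portion used is the
    one starting inside the track (track start .. winter_end for the
    leading winter)."""
    year = track.start.year
    summer = (
        _doy_to_date(template["summer_start"], year),
        _doy_to_date(template["summer_end"], year),
    )
    winter_end = _doy_to_date(template["winter_end"], year)
    winter = (track.start.date(), winter_end)
    return SeasonWindow(
        animal_id=track.animal_id,
        winter=winter,
        summer=summer,
        provenance="resident-percentile",
    )
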