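"""Elevation-use series and altitudinal-migration classification.

From the elevation-annotated fixes we build daily mean elevations and a
centred 14-day moving mean (the smoothing that makes seasonal phases
visible above day-to-day terrain noise), then classify the year's
pattern:

* traditional altitudinal migration — the winter and summer median
  elevations differ by more than 250 m (low winter / high summer in the
  classic case; the sign convention is delta = winter - summer, negative
  when summer is higher);
* abbreviated altitudinal migration — high winter AND summer ranges with
  a spring descent (both seasonal medians more than 150 m above the
  spring moving-mean minimum) and a fall descent (both medians more than
  100 m above the fall minimum);
* altitudinal residency — the moving mean stays inside a 150 m envelope
  all year;
* anything else is reported as "mixed" with a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .config import AltitudeConfig
from .displacement import SeasonWindow
from .telemetry_io import Track

log = logging.getLogger(__name__)

PATTERN_TRADITIONAL = "traditional"
PATTERN_ABBREVIATED = "abbreviated"
PATTERN_RESIDENT = "altitudinal-resident"
PATTERN_MIXED = "mixed"


@dataclass
class ElevationSeries:
    animal_id: str
    daily_mean: pd.Series       # per calendar day, m
    moving_mean: pd.Series      # centred 14-day window, m
    winter_median_m: float
    summer_median_m: float
    winter_range_m: tuple[float, float]
    summer_range_m: tuple[float, float]

    @property
    def delta_winter_summer_m(self) -> float:
        """Winter median minus summer median (negative when the summer
        range is higher)."""
        return self.winter_median_m - self.summer_median_m


@dataclass
class AltitudinalVerdict:
    animal_id: str
    pattern: str
    delta_winter_summer_m: float
    spring_descent_m: float | None = None
    summer_ascent_m: float | None = None
    fall_descent_m: float | None = None
    winter_ascent_m: float | None = None
    flagged: bool = False


def _season_fixes(track: Track, window: tuple[date, date]) -> pd.DataFrame:
    start, end = window
    if start <= end:
        return track.between(start, end)
    # wrapped winter (e.g. Oct..Jun): take both tails within the track
    t = track.fixes["t"]
    doy = pd.DatetimeIndex(t).dayofyear
    s_doy = start.timetuple().tm_yday
    e_doy = end.timetuple().tm_yday
    m = (doy >= s_doy) | (doy <= e_doy)
    return track.fixes.loc[np.asarray(m)]


def elevation_series(
    track: Track,
    windows: SeasonWindow,
    cfg: AltitudeConfig | None = None,
) -> ElevationSeries:
    """Daily and 14-day moving mean elevations plus seasonal medians
    (medians over per-fix elevations inside each season window)."""
    cfg = cfg or AltitudeConfig()
    elev = track.fixes["elev_m"]
    if elev.notna().sum() == 0:
        raise ValueError(f"track {track.animal_id}: no elevations annotated")
    f = track.fixes.loc[elev.notna()]
    daily = (
        pd.Series(
            f["elev_m"].to_numpy(),
            index=pd.DatetimeIndex(f["t"]).normalize(),
        )
        .groupby(level=0)
        .mean()
    )
    daily = daily.reindex(
        pd.date_range(daily.index[0], daily.index[-1], freq="D")
    )
    half = cfg.window_days // 2
    moving = daily.rolling(
        window=2 * half + 1, center=True, min_periods=1
    ).mean()
    # a data gap longer than the window leaves the moving mean undefined
    no_obs = daily.isna().rolling(2 * half + 1, center=True).min() == 1
    moving[no_obs.fillna(False)] = np.nan

    def med_range(window):
        sub = _season_fixes(track, window)
        e = sub["elev_m"].dropna()
        if e.empty:
            return np.nan, (np.nan, np.nan)
        return float(e.median()), (float(e.min()), float(e.max()))

    w_med, w_rng = med_range(windows.winter)
    s_med, s_rng = med_range(windows.summer)
    return ElevationSeries(
        animal_id=track.animal_id,
        daily_mean=daily,
        moving_mean=moving,
        winter_median_m=w_med,
        summer_median_m=s_med,
        winter_range_m=w_rng,
        summer_range_m=s_rng,
    )


def _phase_min(
    moving: pd.Series, start: date, end: date
) -> float | None:
    sub = moving[pd.Timestamp(start):pd.Timestamp(end)].dropna()
    if sub.empty:
        return None
    return float(sub.min())


def classify_altitudinal(
    series: ElevationSeries,
    windows: SeasonWindow,
    cfg: AltitudeConfig | None = None,
) -> AltitudinalVerdict:
    """Apply the threshold taxonomy to a full-year elevation series.

    The spring (fall) phase minimum is searched in a window around the
    transition into (out of) summer; residents get a longer pre-summer
    lead because their descent is not anchored to detected migration
    dates.
    """
    cfg = cfg or AltitudeConfig()
    w_med, s_med = series.winter_median_m, series.summer_median_m
    if np.isnan(w_med) or np.isnan(s_med):
        return AltitudinalVerdict(
            animal_id=series.animal_id,
            pattern=PATTERN_MIXED,
            delta_winter_summer_m=np.nan,
            flagged=True,
        )
    delta = w_med - s_med

    if abs(delta) > cfg.traditional_delta_m:
        return AltitudinalVerdict(
            animal_id=series.animal_id,
            pattern=PATTERN_TRADITIONAL,
            delta_winter_summer_m=delta,
        )

    resident = windows.provenance == "resident-percentile"
    lead = cfg.resident_phase_lead_days if resident else cfg.phase_pad_days
    pad = cfg.phase_pad_days
    summer_start, summer_end = windows.summer
    spring_min = _phase_min(
        series.moving_mean,
        summer_start - timedelta(days=lead),
        summer_start + timedelta(days=pad),
    )
    fall_min = _phase_min(
        series.moving_mean,
        summer_end - timedelta(days=pad),
        summer_end + timedelta(days=lead),
    )
    if spring_min is not None and fall_min is not None:
        spring_desc = w_med - spring_min
        summer_asc = s_med - spring_min
        fall_desc = s_med - fall_min
        winter_asc = w_med - fall_min
        if (
            spring_desc > cfg.spring_delta_m
            and summer_asc > cfg.spring_delta_m
            and fall_desc > cfg.fall_delta_m
            and winter_asc > cfg.fall_delta_m
        ):
            return AltitudinalVerdict(
                animal_id=series.animal_id,
                pattern=PATTERN_ABBREVIATED,
                delta_winter_summer_m=delta,
                spring_descent_m=spring_desc,
                summer_ascent_m=summer_asc,
                fall_descent_m=fall_desc,
                winter_ascent_m=winter_asc,
            )

    mm = series.moving_mean.dropna()
    if len(mm) and float(mm.max() - mm.min()) <= cfg.resident_envelope_m:
        return AltitudinalVerdict(
            animal_id=series.animal_id,
            pattern=PATTERN_RESIDENT,
            delta_winter_summer_m=delta,
        )
    log.info("track %s: mixed altitudinal pattern", series.animal_id)
    return AltitudinalVerdict(
        animal_id=series.animal_id,
        pattern=PATTERN_MIXED,
        delta_winter_summer_m=delta,
        flagged=True,
    )
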