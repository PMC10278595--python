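"""Reading, validating, cleaning and elevation-annotating collar fixes.

A *fix* is one timestamped GPS relocation; a :class:`Track` is an animal's
time-ordered series of retained fixes in a metric CRS, carried as a pandas
DataFrame, together with the fixes that were rejected and why.  Cleaning
follows the usual collar screening sequence: a post-capture exclusion
window, a minimum satellite count, and an iterative forward speed filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .config import CleaningConfig, ColumnMap
from .projection import is_projected_crs, project
from .raster import ELEV_MAX_M, ELEV_MIN_M, DemRaster

log = logging.getLogger(__name__)

FIX_COLUMNS = ["t", "x", "y", "lon", "lat", "n_sats", "elev_m"]

# qc_flag values
FLAG_BAD_RECORD = "unparseable"
FLAG_DUPLICATE_TIME = "duplicate_timestamp"
FLAG_POST_CAPTURE = "post_capture_window"
FLAG_LOW_SATS = "low_satellites"
FLAG_SPEED = "speed_filter"
FLAG_OUTSIDE_DEM = "outside_dem"


@dataclass
class Track:
    """One animal's retained fixes plus its rejected-fix audit trail."""

    animal_id: str
    fixes: pd.DataFrame
    crs: str
    capture_date: date | None = None
    nominal_interval_h: float | None = None
    flagged: pd.DataFrame = field(
        default_factory=lambda: _empty_fix_frame(flagged=True)
    )
    usable: bool = True

    def __post_init__(self) -> None:
        t = self.fixes["t"]
        if len(t) > 1 and not t.is_monotonic_increasing:
            raise ValueError(f"track {self.animal_id}: fixes not time-sorted")
        if not np.isfinite(self.fixes[["x", "y"]].to_numpy()).all():
            raise ValueError(f"track {self.animal_id}: non-finite coordinates")
        elev = self.fixes["elev_m"].dropna()
        if len(elev) and ((elev < ELEV_MIN_M) | (elev > ELEV_MAX_M)).any():
            raise ValueError(f"track {self.animal_id}: implausible elevation")

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    @property
    def start(self) -> pd.Timestamp:
        return self.fixes["t"].iloc[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.fixes["t"].iloc[-1]

    def between(self, start, end) -> pd.DataFrame:
        """Fixes with start <= t <= end (dates are treated as whole days)."""
        t0, t1 = _as_window(start, end)
        m = (self.fixes["t"] >= t0) & (self.fixes["t"] <= t1)
        return self.fixes.loc[m]


def _as_window(start, end) -> tuple[pd.Timestamp, pd.Timestamp]:
    t0 = pd.Timestamp(start)
    t1 = pd.Timestamp(end)
    if t1 == t1.normalize():  # bare date: include the whole day
        t1 = t1 + pd.Timedelta(days=1) - pd.Timedelta(seconds=1)
    return t0, t1


def _empty_fix_frame(flagged: bool = False) -> pd.DataFrame:
    cols = FIX_COLUMNS + (["qc_flag"] if flagged else [])
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in cols})
    df["t"] = pd.Series(dtype="datetime64[ns]")
    if flagged:
        df["qc_flag"] = pd.Series(dtype=object)
    return df


def read_fixes(
    path,
    crs: str,
    columns: ColumnMap | None = None,
    capture_dates: dict[str, date] | None = None,
    sep: str = ",",
) -> list[Track]:
    """Read a delimited-text fix file into one time-sorted Track per animal.

    Geographic coordinates are reprojected into ``crs``; records with
    unparseable timestamps or coordinates are rejected individually (with a
    qc_flag); duplicate timestamps keep the first record.  Raises if no
    valid record survives at all.
    """
    columns = columns or ColumnMap()
    raw = pd.read_csv(path, sep=sep)
    missing = [
        c
        for c in (columns.animal_id, columns.timestamp, columns.x, columns.y)
        if c not in raw.columns
    ]
    if missing:
        native = {"animal_id", "t", "x", "y"}
        if native.issubset(raw.columns):
            # this package's own cleaned-fixes format (already projected)
            columns = ColumnMap(
                animal_id="animal_id", timestamp="t", x="x", y="y",
                n_sats="n_sats" if "n_sats" in raw.columns else None,
                geographic=False,
            )
        else:
            raise ValueError(f"input file lacks required columns: {missing}")

    df = pd.DataFrame(
        {
            "animal_id": raw[columns.animal_id].astype(str),
            "t": pd.to_datetime(
                raw[columns.timestamp], errors="coerce", utc=True
            ).dt.tz_localize(None),
            "cx": pd.to_numeric(raw[columns.x], errors="coerce"),
            "cy": pd.to_numeric(raw[columns.y], errors="coerce"),
        }
    )
    if columns.n_sats and columns.n_sats in raw.columns:
        df["n_sats"] = pd.to_numeric(raw[columns.n_sats], errors="coerce")
    else:
        df["n_sats"] = np.nan
        if columns.n_sats:
            log.warning(
                "no %r column; satellite-count filter will be skipped",
                columns.n_sats,
            )

    bad = df["t"].isna() | df["cx"].isna() | df["cy"].isna()
    n_bad = int(bad.sum())
    if n_bad:
        log.info("rejected %d unparseable records", n_bad)
    if bad.all():
        raise ValueError("no valid records in input file")

    geographic = columns.geographic and not is_projected_crs(crs)
    tracks = []
    for animal_id, grp in df.groupby("animal_id", sort=True):
        good = grp.loc[~bad.loc[grp.index]].sort_values("t", kind="stable")
        dup = good["t"].duplicated(keep="first")
        rejected = pd.concat(
            [
                grp.loc[bad.loc[grp.index]].assign(qc_flag=FLAG_BAD_RECORD),
                good.loc[dup].assign(qc_flag=FLAG_DUPLICATE_TIME),
            ]
        )
        good = good.loc[~dup]
        if geographic:
            x, y = project(good["cx"].to_numpy(), good["cy"].to_numpy(), crs)
            lon, lat = good["cx"].to_numpy(), good["cy"].to_numpy()
        else:
            x, y = good["cx"].to_numpy(), good["cy"].to_numpy()
            lon = lat = np.full(len(good), np.nan)
        fixes = pd.DataFrame(
            {
                "t": good["t"].to_numpy(),
                "x": x,
                "y": y,
                "lon": lon,
                "lat": lat,
                "n_sats": good["n_sats"].to_numpy(),
                "elev_m": np.nan,
            }
        ).reset_index(drop=True)
        flagged = _flag_frame(rejected, geographic)
        interval = _nominal_interval_h(fixes["t"])
        tracks.append(
            Track(
                animal_id=str(animal_id),
                fixes=fixes,
                crs=crs,
                capture_date=(capture_dates or {}).get(str(animal_id)),
                nominal_interval_h=interval,
                flagged=flagged,
            )
        )
    return tracks


def _flag_frame(rejected: pd.DataFrame, geographic: bool) -> pd.DataFrame:
    if rejected.empty:
        return _empty_fix_frame(flagged=True)
    out = _empty_fix_frame(flagged=True)
    out = pd.DataFrame(
        {
            "t": rejected["t"].to_numpy(),
            "x": np.nan,
            "y": np.nan,
            "lon": rejected["cx"].to_numpy() if geographic else np.nan,
            "lat": rejected["cy"].to_numpy() if geographic else np.nan,
            "n_sats": rejected["n_sats"].to_numpy(),
            "elev_m": np.nan,
            "qc_flag": rejected["qc_flag"].to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def _nominal_interval_h(t: pd.Series) -> float | None:
    if len(t) < 2:
        return None
    dt_h = np.diff(t.to_numpy()).astype("timedelta64[s]").astype(float) / 3600
    return float(np.median(dt_h))


def clean_track(
    track: Track, capture_date: date | None = None, cfg: CleaningConfig | None = None
) -> Track:
    """Apply the post-capture, satellite-count and speed screens.

    The speed filter runs in a single forward pass against the previous
    *retained* fix, so one positional blunder cannot cascade into the
    rejection of the legitimate fixes that follow it.  A track left with
    fewer than ``cfg.min_fixes`` survivors is marked unusable rather than
    raising.
    """
    cfg = cfg or CleaningConfig()
    capture_date = capture_date or track.capture_date
    fixes = track.fixes
    reasons = np.full(len(fixes), None, dtype=object)

    if capture_date is not None:
        cutoff = pd.Timestamp(capture_date) + timedelta(
            days=cfg.post_capture_days
        )
        reasons[(fixes["t"] < cutoff).to_numpy()] = FLAG_POST_CAPTURE

    sats = fixes["n_sats"].to_numpy()
    if np.isnan(sats).all():
        log.warning(
            "track %s: no satellite counts, skipping satellite filter",
            track.animal_id,
        )
    else:
        low = (sats <= cfg.min_sats_exclusive) & (reasons == None)  # noqa: E711
        reasons[low] = FLAG_LOW_SATS

    # iterative forward speed screen against the last retained fix
    x = fixes["x"].to_numpy()
    y = fixes["y"].to_numpy()
    t = fixes["t"].to_numpy().astype("datetime64[s]").astype(float)
    prev = None
    for i in range(len(fixes)):
        if reasons[i] is not None:
            continue
        if prev is not None:
            dt_h = (t[i] - t[prev]) / 3600.0
            if dt_h > 0:
                d_km = np.hypot(x[i] - x[prev], y[i] - y[prev]) / 1000.0
                if d_km / dt_h > cfg.max_speed_kmh:
                    reasons[i] = FLAG_SPEED
                    continue
        prev = i

    keep = reasons == None  # noqa: E711
    removed = fixes.loc[~keep].assign(qc_flag=reasons[~keep])
    flagged = pd.concat([track.flagged, removed], ignore_index=True)
    cleaned = replace(
        track,
        fixes=fixes.loc[keep].reset_index(drop=True),
        capture_date=capture_date,
        flagged=flagged,
        usable=int(keep.sum()) >= cfg.min_fixes,
    )
    if not cleaned.usable:
        log.warning(
            "track %s: only %d fixes after cleaning, flagged unusable",
            track.animal_id,
            cleaned.n_fixes,
        )
    return cleaned


def coverage_adequate(
    track: Track,
    spring_start: date | None,
    fall_end: date | None,
    lead_days: int = 30,
    trail_days: int = 90,
) -> bool:
    """True when the series brackets the migration cycle: it begins at
    least ``lead_days`` before spring departure and ends at least
    ``trail_days`` after the fall return.  Residents (null dates) are
    adequate whenever the series spans a full year."""
    if spring_start is None or fall_end is None:
        return (track.end - track.start) >= pd.Timedelta(days=365)
    return (
        track.start <= pd.Timestamp(spring_start) - pd.Timedelta(days=lead_days)
        and track.end >= pd.Timestamp(fall_end) + pd.Timedelta(days=trail_days)
    )


def annotate_elevation(track: Track, dem: DemRaster) -> Track:
    """Fill ``elev_m`` from the DEM cell containing each fix.

    Fixes outside the DEM extent keep elev_m unset and are recorded in the
    flagged frame (they stay in the track for geometric analyses but are
    excluded from elevation analyses).
    """
    fixes = track.fixes.copy()
    elev = dem.sample(fixes["x"].to_numpy(), fixes["y"].to_numpy())
    fixes["elev_m"] = elev
    outside = np.isnan(elev)
    flagged = track.flagged
    if outside.any():
        log.warning(
            "track %s: %d fixes outside DEM extent",
            track.animal_id,
            int(outside.sum()),
        )
        flagged = pd.concat(
            [flagged, fixes.loc[outside].assign(qc_flag=FLAG_OUTSIDE_DEM)],
            ignore_index=True,
        )
    return replace(track, fixes=fixes, flagged=flagged)


def write_fixes(tracks: list[Track], path) -> None:
    """Write retained and flagged fixes of all tracks to one CSV, with a
    qc_flags column that is empty for retained fixes."""
    frames = []
    for tr in tracks:
        kept = tr.fixes.assign(animal_id=tr.animal_id, qc_flag="")
        bad = tr.flagged.assign(animal_id=tr.animal_id)
        frames.extend([kept, bad])
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["animal_id", "t"], kind="stable")
    cols = ["animal_id"] + FIX_COLUMNS + ["qc_flag"]
    out.to_csv(path, index=False, columns=cols)
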