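"""Migration-strategy classification, cohort summaries and the pipeline
driver.

The six-way label taxonomy:

* geographic migrants (distinct summer range, summer-on-winter overlap
  under 20%) are long-distance (route > 20 km) or short-distance
  migrants, except that two or more summer returns to the winter range
  reclassify them as vacillating migrants;
* geographic residents are labelled by their altitudinal pattern:
  traditional altitudinal migrant, abbreviated altitudinal migrant, or
  resident.

The geographic label takes precedence over any concurrent altitudinal
pattern.  A route distance of exactly 20 km is short-distance (the
cut-off is read as "greater than" for long-distance).
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from shapely.geometry import mapping

from . import __version__
from .altitude import (
    PATTERN_ABBREVIATED,
    PATTERN_RESIDENT,
    PATTERN_TRADITIONAL,
    AltitudinalVerdict,
    classify_altitudinal,
    elevation_series,
)
from .bbmm_core import RangePolygon
from .config import PipelineConfig
from .corridors import (
    Corridor,
    StopoverSite,
    band_corridor,
    corridor_ud,
    extract_stopovers,
    route_distance,
)
from .displacement import (
    MigrationEvent,
    SeasonWindow,
    compute_nsd,
    count_vacillations,
    detect_migration,
    resident_seasons,
    season_windows_for_migrant,
    season_windows_for_resident,
    template_from_config,
)
from .ranges import assign_bands, is_geographic_migrant, overlap, seasonal_range
from .raster import DemRaster
from .telemetry_io import Track, clean_track, write_fixes

log = logging.getLogger(__name__)


class StrategyLabel(str, enum.Enum):
    LDM = "LDM"            # long-distance geographic migrant
    SDM = "SDM"            # short-distance geographic migrant
    VAC = "VAC"            # vacillating migrant
    TRAD_ALT = "TRAD_ALT"  # traditional altitudinal migrant
    ABR_ALT = "ABR_ALT"    # abbreviated altitudinal migrant
    RESIDENT = "RESIDENT"


def classify_strategy(
    geo_migrant: bool,
    n_vacillations: int,
    distance_km: float | None,
    alt_pattern: str | None,
    long_distance_km: float = 20.0,
) -> StrategyLabel:
    """Total decision tree over the upstream verdicts.

    ``alt_pattern`` is one of the altitude module's pattern strings (or
    None when elevations were unavailable); a mixed/unknown pattern for a
    geographic resident falls back to RESIDENT with a log note.
    """
    if geo_migrant:
        if n_vacillations >= 2:
            return StrategyLabel.VAC
        if distance_km is None:
            raise ValueError("migrant lacks a route distance")
        if distance_km > long_distance_km:
            return StrategyLabel.LDM
        return StrategyLabel.SDM
    if alt_pattern == PATTERN_TRADITIONAL:
        return StrategyLabel.TRAD_ALT
    if alt_pattern == PATTERN_ABBREVIATED:
        return StrategyLabel.ABR_ALT
    if alt_pattern not in (PATTERN_RESIDENT, None):
        log.info("unresolved altitudinal pattern %r -> RESIDENT", alt_pattern)
    return StrategyLabel.RESIDENT


# ---------------------------------------------------------------------------
# cohort analysis

@dataclass
class AnimalResult:
    animal_id: str
    label: StrategyLabel | None = None
    geo_migrant: bool = False
    event: MigrationEvent | None = None
    windows: SeasonWindow | None = None
    winter_range: RangePolygon | None = None
    summer_range: RangePolygon | None = None
    overlap_pct: float | None = None
    overlap_ha: float | None = None
    distance_km: float | None = None
    n_vacillations: int = 0
    alt_verdict: AltitudinalVerdict | None = None
    corridors: dict[str, Corridor] = field(default_factory=dict)
    stopovers: dict[str, list[StopoverSite]] = field(default_factory=dict)
    usable: bool = True
    note: str = ""


@dataclass
class CohortResult:
    results: dict[str, AnimalResult]
    season_template: dict[str, int]
    bands: list[set[str]] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        rows = []
        for r in self.results.values():
            av = r.alt_verdict
            ev = r.event
            rows.append(
                {
                    "animal_id": r.animal_id,
                    "label": r.label.value if r.label else None,
                    "geo_migrant": r.geo_migrant,
                    "spring_start": ev.spring_start if ev else None,
                    "spring_end": ev.spring_end if ev else None,
                    "fall_start": ev.fall_start if ev else None,
                    "fall_end": ev.fall_end if ev else None,
                    "n_vacillations": r.n_vacillations,
                    "winter_ha": (
                        round(r.winter_range.area_ha, 1)
                        if r.winter_range
                        else None
                    ),
                    "summer_ha": (
                        round(r.summer_range.area_ha, 1)
                        if r.summer_range
                        else None
                    ),
                    "overlap_pct": (
                        round(r.overlap_pct, 1)
                        if r.overlap_pct is not None
                        else None
                    ),
                    "overlap_ha": (
                        round(r.overlap_ha, 1)
                        if r.overlap_ha is not None
                        else None
                    ),
                    "distance_km": (
                        round(r.distance_km, 1)
                        if r.distance_km is not None
                        else None
                    ),
                    "delta_elev_m": (
                        round(av.delta_winter_summer_m, 1) if av else None
                    ),
                    "alt_pattern": av.pattern if av else None,
                    "usable": r.usable,
                    "note": r.note,
                }
            )
        return pd.DataFrame(rows).sort_values("animal_id").reset_index(
            drop=True
        )


def _reference_date(cfg: PipelineConfig, track: Track) -> date:
    ref = cfg.reference_date(track.start.year)
    if track.capture_date is not None:
        post = track.capture_date + pd.Timedelta(
            days=cfg.cleaning.post_capture_days
        ).to_pytimedelta()
        ref = max(ref, post)
    return max(ref, track.start.date())


def analyze_cohort(
    tracks: list[Track],
    cfg: PipelineConfig | None = None,
    dem: DemRaster | None = None,
    dems: dict[str, DemRaster] | None = None,
    clean: bool = True,
    with_corridors: bool = False,
) -> CohortResult:
    """Run the classification chain for a cohort of tracks.

    Stages: cleaning -> NSD migration detection -> percentile season
    template -> seasonal ranges and the overlap rule -> vacillation
    counting -> route distances -> elevation series and altitudinal
    pattern -> strategy label.  Corridor/stopover extraction is optional
    because only mapping products need it.
    """
    cfg = cfg or PipelineConfig()
    results: dict[str, AnimalResult] = {}
    prepared: dict[str, Track] = {}

    from .telemetry_io import annotate_elevation

    for tr in tracks:
        r = AnimalResult(animal_id=tr.animal_id)
        results[tr.animal_id] = r
        t = clean_track(tr, cfg=cfg.cleaning) if clean else tr
        if not t.usable:
            r.usable = False
            r.note = "too few fixes after cleaning"
            continue
        d = (dems or {}).get(tr.animal_id, dem)
        if d is not None:
            t = annotate_elevation(t, d)
        prepared[tr.animal_id] = t

    # migration detection
    events: dict[str, MigrationEvent] = {}
    for aid, t in prepared.items():
        try:
            series = compute_nsd(t, _reference_date(cfg, t))
            ev = detect_migration(series, cfg.detector)
        except ValueError as exc:
            results[aid].usable = False
            results[aid].note = str(exc)
            continue
        if ev is not None:
            events[aid] = ev
            results[aid].event = ev

    # resident season template
    confirmed = [e for e in events.values() if e.fall_end is not None]
    if len(confirmed) >= 3:
        template = resident_seasons(confirmed)
    else:
        year = tracks[0].start.year if tracks else date.today().year
        template = template_from_config(cfg.season_template, year)

    # seasonal ranges, overlap rule, vacillations, distances, altitude
    for aid, t in prepared.items():
        r = results[aid]
        if not r.usable:
            continue
        ev = events.get(aid)
        if ev is not None:
            r.windows = season_windows_for_migrant(t, ev)
        else:
            r.windows = season_windows_for_resident(t, template)
        r.winter_range = seasonal_range(
            t, r.windows.winter, "winter", cfg.bbmm, cfg.ranges
        )
        r.summer_range = seasonal_range(
            t, r.windows.summer, "summer", cfg.bbmm, cfg.ranges
        )
        if r.winter_range and r.summer_range:
            ov = overlap(r.summer_range, r.winter_range)
            r.overlap_pct = ov.pct_of_second  # summer-on-winter
            r.overlap_ha = ov.area_ha
        r.geo_migrant = (
            ev is not None
            and r.overlap_pct is not None
            and is_geographic_migrant(
                r.overlap_pct, cfg.ranges.migrant_max_overlap_pct
            )
        )
        if r.geo_migrant and r.winter_range is not None:
            r.n_vacillations = count_vacillations(
                t, ev, r.winter_range, cfg.detector.min_return_fixes
            )
        if ev is not None:
            spring_d = route_distance(t, ev, "spring")
            fall_d = route_distance(t, ev, "fall")
            primary = (
                spring_d if cfg.corridors.distance_season == "spring" else fall_d
            )
            fallback = fall_d if cfg.corridors.distance_season == "spring" else spring_d
            r.distance_km = (
                primary if primary and np.isfinite(primary) else fallback
            )
        if t.fixes["elev_m"].notna().any():
            series_e = elevation_series(t, r.windows, cfg.altitude)
            r.alt_verdict = classify_altitudinal(
                series_e, r.windows, cfg.altitude
            )
        r.label = classify_strategy(
            r.geo_migrant,
            r.n_vacillations,
            r.distance_km,
            r.alt_verdict.pattern if r.alt_verdict else None,
            cfg.long_distance_km,
        )
        if with_corridors and r.geo_migrant:
            seasons = ["spring"] + (["fall"] if ev.fall_end else [])
            for season in seasons:
                try:
                    c = corridor_ud(t, ev, season, cfg.bbmm, cfg.corridors)
                except ValueError as exc:
                    log.warning("%s %s corridor: %s", aid, season, exc)
                    continue
                r.corridors[season] = c
                r.stopovers[season] = extract_stopovers(
                    c,
                    t,
                    [r.winter_range, r.summer_range],
                    cfg.corridors,
                )

    # band partition from winter ranges + co-movement
    winter_ranges = {
        aid: r.winter_range
        for aid, r in results.items()
        if r.winter_range is not None
    }
    bands = (
        assign_bands(
            winter_ranges,
            {aid: prepared[aid] for aid in winter_ranges},
            cfg.ranges,
        )
        if winter_ranges
        else []
    )
    return CohortResult(results=results, season_template=template, bands=bands)


# ---------------------------------------------------------------------------
# cohort summaries

def summarize_cohort(
    records: pd.DataFrame,
    value_cols: list[str] | None = None,
    group_col: str | None = None,
) -> pd.DataFrame:
    """Median / min / max / P33 / P66 with n, per statistic (optionally
    per group).  Percentiles use linear interpolation, so the even-n
    median is the mean of the two central order statistics."""
    if value_cols is None:
        value_cols = [
            c for c in records.columns
            if pd.api.types.is_numeric_dtype(records[c])
        ]
    groups = (
        records.groupby(group_col) if group_col else [("all", records)]
    )
    rows = []
    for gname, gdf in groups:
        for col in value_cols:
            v = pd.to_numeric(gdf[col], errors="coerce").dropna().to_numpy()
            if len(v) == 0:
                continue
            rows.append(
                {
                    "group": gname,
                    "statistic": col,
                    "n": len(v),
                    "median": float(np.percentile(v, 50)),
                    "min": float(v.min()),
                    "max": float(v.max()),
                    "p33": float(np.percentile(v, 33)),
                    "p66": float(np.percentile(v, 66)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# published per-animal reference table (16 collared females, 9 bands)

def load_reference_table() -> pd.DataFrame:
    """The published per-animal summary rows (seasonal range areas in ha,
    summer-on-winter overlap, route distance in km, winter-minus-summer
    median-elevation change in m, reported summer-return counts for the
    two vacillating females, and the printed strategy column)."""
    ref = importlib.resources.files("ovitrack.data") / "reference_cohort.csv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p)


def classify_reference_row(
    row: pd.Series, long_distance_km: float = 20.0
) -> StrategyLabel:
    """Apply the decision tree to one published summary row."""
    migrant = is_geographic_migrant(float(row["overlap_pct"]))
    distance = row.get("distance_km")
    distance = None if pd.isna(distance) else float(distance)
    if migrant:
        alt = None
    else:
        delta = float(row["delta_elev_m"])
        alt = (
            PATTERN_TRADITIONAL if abs(delta) > 250.0 else PATTERN_ABBREVIATED
        )
        # published residents all showed the abbreviated pattern
    return classify_strategy(
        migrant, int(row["n_returns"]), distance, alt, long_distance_km
    )


# ---------------------------------------------------------------------------
# pipeline driver and writers

def _range_feature(r: RangePolygon, props: dict) -> dict:
    return {
        "type": "Feature",
        "properties": props,
        "geometry": mapping(r.polygon),
    }


def write_geojson(features: list[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"type": "FeatureCollection", "features": features}, fh
        )


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(
        dataclasses.asdict(cfg), default=str, sort_keys=True
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(
    tracks: list[Track],
    cfg: PipelineConfig,
    outdir,
    dem: DemRaster | None = None,
    dems: dict[str, DemRaster] | None = None,
    seed: int | None = None,
    make_plots: bool = False,
) -> CohortResult:
    """Full run: analysis chain plus corridor/stopover extraction and all
    file outputs (CSV tables, GeoJSON geometries, run manifest)."""
    from pathlib import Path

    if not tracks:
        raise ValueError("no input tracks")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = analyze_cohort(
        tracks, cfg, dem=dem, dems=dems, with_corridors=True
    )
    table = cohort.table()
    table.to_csv(outdir / "strategies.csv", index=False)

    cleaned = [
        clean_track(t, cfg=cfg.cleaning) for t in tracks
    ]
    write_fixes(cleaned, outdir / "cleaned_fixes.csv")

    ev_rows = [
        {
            "animal_id": r.animal_id,
            "spring_start": r.event.spring_start,
            "spring_end": r.event.spring_end,
            "spring_duration_d": r.event.spring_duration_d,
            "fall_start": r.event.fall_start,
            "fall_end": r.event.fall_end,
            "fall_duration_d": r.event.fall_duration_d,
            "n_vacillations": r.n_vacillations,
            "truncated": r.event.truncated,
        }
        for r in cohort.results.values()
        if r.event is not None
    ]
    pd.DataFrame(ev_rows).to_csv(outdir / "migration_events.csv", index=False)

    mig = table[table["geo_migrant"] == True]  # noqa: E712
    res = table[(table["geo_migrant"] == False) & table["usable"]]  # noqa: E712
    summary = pd.concat(
        [
            summarize_cohort(
                mig, ["winter_ha", "summer_ha", "overlap_pct", "distance_km"]
            ).assign(group="migrants"),
            summarize_cohort(
                res, ["winter_ha", "summer_ha", "overlap_pct"]
            ).assign(group="residents"),
        ],
        ignore_index=True,
    )
    summary.to_csv(outdir / "cohort_summary.csv", index=False)

    features = []
    for r in cohort.results.values():
        for rng, season in ((r.winter_range, "winter"), (r.summer_range, "summer")):
            if rng is None:
                continue
            features.append(
                _range_feature(
                    rng,
                    {
                        "animal_id": r.animal_id,
                        "season": season,
                        "q": rng.q,
                        "area_ha": round(rng.area_ha, 1),
                    },
                )
            )
    write_geojson(features, outdir / "seasonal_ranges.geojson")

    corridor_features, stop_rows = [], []
    for r in cohort.results.values():
        for season, c in r.corridors.items():
            corridor_features.append(
                _range_feature(
                    c.polygon95,
                    {
                        "animal_id": r.animal_id,
                        "season": season,
                        "route_distance_km": round(c.route_distance_km, 1),
                    },
                )
            )
        for season, sites in r.stopovers.items():
            for s in sites:
                cx, cy = s.centroid
                stop_rows.append(
                    {
                        "animal_id": r.animal_id,
                        "season": season,
                        "site_id": s.site_id,
                        "area_ha": round(s.area_ha, 1),
                        "occupancy_h": round(
                            s.occupancy.get(r.animal_id, 0.0), 1
                        ),
                        "centroid_x": round(cx, 1),
                        "centroid_y": round(cy, 1),
                    }
                )
    write_geojson(corridor_features, outdir / "corridors.geojson")
    pd.DataFrame(stop_rows).to_csv(outdir / "stopovers.csv", index=False)

    # combined band corridors where several members migrated
    band_rows = []
    for i, members in enumerate(cohort.bands):
        band_rows.extend(
            {"band": i + 1, "animal_id": aid} for aid in sorted(members)
        )
        spring = [
            cohort.results[aid].corridors["spring"]
            for aid in members
            if "spring" in cohort.results[aid].corridors
        ]
        if len(spring) > 1:
            band_corridor(spring)  # validates combinability
    pd.DataFrame(band_rows).to_csv(outdir / "bands.csv", index=False)

    if make_plots:
        from . import plots

        for tr in cleaned:
            if not tr.usable:
                continue
            try:
                series = compute_nsd(tr, _reference_date(cfg, tr))
            except ValueError:
                continue
            plots.plot_nsd(
                series,
                cohort.results[tr.animal_id].event,
                outdir / f"nsd_{tr.animal_id}.png",
            )

    manifest = {
        "package": "ovitrack",
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "n_tracks": len(tracks),
        "n_usable": int(table["usable"].sum()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return cohort
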