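"""Threshold and parameter configuration for the analysis pipeline.

Every decision rule in the pipeline (cleaning filters, migration detector,
Brownian bridge parameters, band/fidelity overlap cut-offs, stopover rules,
altitudinal thresholds) is driven by a named constant collected here, so a
whole run is reproducible from one structured config file plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date

import yaml


@dataclass
class CleaningConfig:
    """Raw-fix screening thresholds.

    post_capture_days
        Fixes within this many days of the capture date are dropped
        (handling/anaesthesia can bias early movement).
    min_sats_exclusive
        Fixes acquired with this many satellites or fewer are dropped.
    max_speed_kmh
        Straight-line speed from the previous retained fix above which a
        fix is treated as a positional blunder.
    min_fixes
        Below this many survivors the animal is flagged unusable.
    """

    post_capture_days: int = 7
    min_sats_exclusive: int = 2
    max_speed_kmh: float = 20.0
    min_fixes: int = 100


@dataclass
class DetectorConfig:
    """Net-squared-displacement migration detector constants.

    The detector is a deterministic surrogate for the visual NSD
    inspection traditionally used to pick migration dates; every constant
    is exposed so the surrogate is auditable.
    """

    reference_month: int = 3
    reference_day: int = 15
    winter_radius_days: int = 30        # days after reference used for r_w
    winter_radius_pct: float = 95.0     # percentile of sqrt(NSD) for r_w
    plateau_frac: float = 0.5           # candidate-day threshold vs P95 NSD
    plateau_pct: float = 95.0
    min_plateau_days: int = 30          # sustained distinct-range occupancy
    min_separation_factor: float = 2.0  # plateau displacement vs r_w
    min_run_days: int = 3               # ignore shorter above-threshold blips
    arrival_frac: float = 0.85          # date refinement level vs plateau NSD
    return_window_days: int = 30        # confirmation window after fall end
                                        # (its median NSD must be in-range)
    min_return_fixes: int = 6           # consecutive in-winter fixes = 1 return


@dataclass
class BBMMConfig:
    """Brownian bridge movement model parameters."""

    cell_m: float = 50.0
    sigma2_m: float = 30.0              # GPS location error SD
    n_alpha: int = 10                   # time-integration steps per bridge
    max_bridge_gap_h: float = 24.0
    sigma1_bounds: tuple[float, float] = (1e-3, 50.0)  # m / sqrt(s)
    trunc_sd: float = 6.0               # per-slice Gaussian support radius


@dataclass
class RangeConfig:
    """Seasonal range, band and fidelity rules."""

    isopleth_q: float = 0.95
    migrant_max_overlap_pct: float = 20.0   # summer-on-winter, strict <
    band_min_overlap_pct: float = 70.0      # of the smaller winter range
    co_movement_frac: float = 0.5
    proximity_m: float = 500.0
    match_tolerance_h: float = 1.0
    fidelity_min_overlap_pct: float = 50.0
    min_window_days: int = 30


@dataclass
class CorridorConfig:
    """Migration corridor and stopover rules."""

    pad_h: float = 24.0                 # fixes included around migration dates
    stopover_q: float = 0.10            # top fraction of the corridor UD
    min_occupancy_h: float = 12.0
    merge_distance_m: float = 300.0
    distance_season: str = "spring"     # reported per-female route distance


@dataclass
class AltitudeConfig:
    """Elevation series and altitudinal-migration thresholds."""

    window_days: int = 14               # centred moving-mean span
    traditional_delta_m: float = 250.0
    spring_delta_m: float = 150.0
    fall_delta_m: float = 100.0
    resident_envelope_m: float = 150.0
    phase_pad_days: int = 14            # phase search pad for migrants
    resident_phase_lead_days: int = 75  # pre-summer search for residents


@dataclass
class SeasonTemplate:
    """Fallback resident season windows (month, day) when fewer than three
    migrant events are available to derive the percentile template."""

    summer_start: tuple[int, int] = (6, 26)
    summer_end: tuple[int, int] = (8, 18)
    winter_start: tuple[int, int] = (10, 5)
    winter_end: tuple[int, int] = (6, 12)


@dataclass
class ColumnMap:
    """Mapping from input delimited-text headers to fix fields.

    Defaults recognise Movebank-style exports.
    """

    animal_id: str = "individual-local-identifier"
    timestamp: str = "timestamp"
    x: str = "location-long"
    y: str = "location-lat"
    n_sats: str | None = "gps:satellite-count"
    geographic: bool = True


@dataclass
class PipelineConfig:
    """Aggregate configuration for a full pipeline run."""

    crs: str = "utm-9n"
    long_distance_km: float = 20.0      # long vs short migration cut-off
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    bbmm: BBMMConfig = field(default_factory=BBMMConfig)
    ranges: RangeConfig = field(default_factory=RangeConfig)
    corridors: CorridorConfig = field(default_factory=CorridorConfig)
    altitude: AltitudeConfig = field(default_factory=AltitudeConfig)
    season_template: SeasonTemplate = field(default_factory=SeasonTemplate)
    columns: ColumnMap = field(default_factory=ColumnMap)

    def reference_date(self, year: int) -> date:
        d = self.detector
        return date(year, d.reference_month, d.reference_day)


def _to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _from_dict(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in _NESTED:
            kwargs[f.name] = _from_dict(_NESTED[f.name], v)
        elif isinstance(v, list):
            kwargs[f.name] = tuple(v)
        else:
            kwargs[f.name] = v
    return cls(**kwargs)


_NESTED = {
    "cleaning": CleaningConfig,
    "detector": DetectorConfig,
    "bbmm": BBMMConfig,
    "ranges": RangeConfig,
    "corridors": CorridorConfig,
    "altitude": AltitudeConfig,
    "season_template": SeasonTemplate,
    "columns": ColumnMap,
}


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(cfg), fh, sort_keys=False)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(PipelineConfig, data)
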