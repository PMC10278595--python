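"""NSD computation, migration-date detection, vacillation counting,
and the percentile season template."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from ovitrack.bbmm_core import RangePolygon
from ovitrack.config import DetectorConfig
from ovitrack.displacement import (
    MigrationEvent,
    compute_nsd,
    count_vacillations,
    detect_migration,
    resident_seasons,
    season_windows_for_migrant,
    template_from_config,
)
from ovitrack.config import SeasonTemplate
from ovitrack.synthetic_data import config_for_strategy, simulate_track
from ovitrack.telemetry_io import Track


class TestComputeNSD:
    def test_stationary_animal_is_zero(self, track_factory):
        tr = track_factory([(0, 0)] * 50, start="2019-03-15")
        s = compute_nsd(tr, date(2019, 3, 15))
        assert np.allclose(s.fix_nsd, 0.0)

    def test_three_four_five_closed_form(self, track_factory):
        tr = track_factory([(0, 0), (3, 4), (6, 8)], start="2019-03-15")
        s = compute_nsd(tr, date(2019, 3, 15))
        np.testing.assert_allclose(s.fix_nsd, [0.0, 25.0, 100.0])

    def test_reference_is_first_fix_at_or_after_date(self, track_factory):
        tr = track_factory([(1, 1)] * 100, start="2019-03-10")
        s = compute_nsd(tr, date(2019, 3, 12))
        assert s.fix_t.iloc[0] >= pd.Timestamp("2019-03-12")
        assert s.fix_nsd[0] == 0.0

    def test_no_fix_near_reference_raises(self, track_factory):
        tr = track_factory([(0, 0)] * 10, start="2019-06-01")
        with pytest.raises(ValueError, match="within 7 days"):
            compute_nsd(tr, date(2019, 3, 15))

    def test_plateau_height_matches_centroid_separation(self):
        """The summer NSD plateau sits at (true separation)^2."""
        for seed in (1, 2, 3):
            cfg = config_for_strategy("LDM", seed)
            track, gt = simulate_track(cfg)
            s = compute_nsd(track, date(2019, 3, 15))
            july = s.smoothed["2019-07-01":"2019-08-15"]
            sep_km = (
                gt.summer_centroid[0] - gt.winter_centroid[0]
            ) / 1000.0
            assert np.median(july) == pytest.approx(sep_km**2, rel=0.05)


class TestDetectMigration:
    @staticmethod
    def _series(track):
        return compute_nsd(track, date(2019, 3, 15))

    def test_resident_gets_no_event(self):
        track, _ = simulate_track(config_for_strategy("RESIDENT", 3))
        assert detect_migration(self._series(track)) is None

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_migrant_dates_within_three_days(self, seed):
        cfg = config_for_strategy("LDM", seed)
        track, gt = simulate_track(cfg)
        ev = detect_migration(self._series(track))
        assert ev is not None
        assert abs((ev.spring_start - gt.spring_depart).days) <= 3
        assert abs((ev.spring_end - gt.spring_arrive).days) <= 3
        assert abs((ev.fall_start - gt.fall_depart).days) <= 3
        assert abs((ev.fall_end - gt.fall_arrive).days) <= 3

    def test_event_dates_are_ordered(self):
        track, _ = simulate_track(config_for_strategy("VAC", 8))
        ev = detect_migration(self._series(track))
        assert ev.spring_start <= ev.spring_end < ev.fall_start
        assert ev.fall_start <= ev.fall_end

    def test_translation_and_rotation_invariance(self):
        track, _ = simulate_track(config_for_strategy("SDM", 6))
        ev0 = detect_migration(self._series(track))

        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        xy = track.fixes[["x", "y"]].to_numpy() @ rot.T + [1e5, -2e5]
        fixes = track.fixes.copy()
        fixes["x"], fixes["y"] = xy[:, 0], xy[:, 1]
        moved = Track(
            animal_id=track.animal_id, fixes=fixes, crs=track.crs
        )
        ev1 = detect_migration(self._series(moved))
        assert (ev0.spring_start, ev0.spring_end, ev0.fall_start, ev0.fall_end) == (
            ev1.spring_start, ev1.spring_end, ev1.fall_start, ev1.fall_end
        )

    def test_truncated_series_flags_unconfirmed_fall(self):
        cfg = config_for_strategy("LDM", 2, end=date(2019, 9, 20))
        track, _ = simulate_track(cfg)
        ev = detect_migration(self._series(track))
        assert ev is not None and ev.truncated

    def test_doubling_fix_frequency_shifts_dates_at_most_one_day(self):
        """On near-noise-free tracks the detected dates are a property of
        the schedule, not of the sampling rate."""
        quiet = dict(
            loc_error_sd_m=0.0,
            residence_sd_m=100.0,
            route_jitter_sd_m=10.0,
            stopover_sd_m=10.0,
        )
        ev = {}
        for ih in (2.0, 1.0):
            cfg = config_for_strategy("SDM", 12, fix_interval_h=ih, **quiet)
            track, _ = simulate_track(cfg)
            ev[ih] = detect_migration(self._series(track))
        for a, b in [
            (ev[2.0].spring_start, ev[1.0].spring_start),
            (ev[2.0].spring_end, ev[1.0].spring_end),
            (ev[2.0].fall_start, ev[1.0].fall_start),
            (ev[2.0].fall_end, ev[1.0].fall_end),
        ]:
            assert abs((a - b).days) <= 1

    def test_season_windows_tile_the_track_span(self):
        track, _ = simulate_track(config_for_strategy("LDM", 9))
        ev = detect_migration(self._series(track))
        w = season_windows_for_migrant(track, ev)
        assert w.winter[1] == ev.spring_start
        assert w.summer == (ev.spring_end, ev.fall_start)
        # winter -> spring migration -> summer -> fall migration partition
        assert w.winter[0] <= w.winter[1] < w.summer[0] < w.summer[1]


class TestVacillations:
    @staticmethod
    def _winter_polygon(center, radius_m=1500.0, cell=50.0):
        gx0 = int(center[0] // cell)
        gy0 = int(center[1] // cell)
        r = int(radius_m // cell)
        cells = {
            (gx0 + i, gy0 + j)
            for i in range(-r, r + 1)
            for j in range(-r, r + 1)
            if i * i + j * j <= r * r
        }
        return RangePolygon(cells=frozenset(cells), cell_m=cell, q=0.95)

    def test_monotone_plateau_has_zero_returns(self):
        track, gt = simulate_track(config_for_strategy("LDM", 4))
        ev = detect_migration(compute_nsd(track, date(2019, 3, 15)))
        poly = self._winter_polygon(gt.winter_centroid)
        assert count_vacillations(track, ev, poly) == 0

    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_planted_returns_are_counted_exactly(self, seed):
        track, gt = simulate_track(config_for_strategy("VAC", seed))
        ev = detect_migration(compute_nsd(track, date(2019, 3, 15)))
        poly = self._winter_polygon(gt.winter_centroid)
        n = count_vacillations(track, ev, poly)
        assert n == gt.n_vacillations == 3
        # two or more returns is the vacillating-migrant criterion
        assert n >= 2


class TestResidentSeasons:
    @staticmethod
    def _event(ss, se, fs, fe):
        return MigrationEvent(
            animal_id="x",
            spring_start=ss,
            spring_end=se,
            fall_start=fs,
            fall_end=fe,
        )

    def test_identical_migrant_dates_reproduce_those_dates(self):
        ev = self._event(
            date(2019, 6, 12), date(2019, 6, 17),
            date(2019, 8, 30), date(2019, 9, 22),
        )
        tpl = resident_seasons([ev, ev, ev])
        assert tpl["summer_start"] == date(2019, 6, 17).timetuple().tm_yday
        assert tpl["summer_end"] == date(2019, 8, 30).timetuple().tm_yday

    def test_linear_interpolation_rounds_half_up(self):
        """Spring starts {d, d+3, d+6}: the 33rd percentile interpolates
        to d+1.98 and rounds to whole day d+2."""
        base = date(2019, 6, 1)
        evs = [
            self._event(
                base.replace(day=1 + 3 * k),
                date(2019, 6, 20),
                date(2019, 8, 30),
                date(2019, 9, 22),
            )
            for k in range(3)
        ]
        tpl = resident_seasons(evs)
        d0 = base.timetuple().tm_yday
        assert tpl["winter_end"] == d0 + 2

    def test_published_percentiles_give_54_day_summer(self):
        """Degenerate events pinned at the published 66th/33rd percentile
        dates (26 Jun spring end, 18 Aug fall start) yield the published
        resident summer window of 54 days."""
        ev = self._event(
            date(2019, 6, 5), date(2019, 6, 26),
            date(2019, 8, 18), date(2019, 10, 5),
        )
        tpl = resident_seasons([ev] * 3)
        length = tpl["summer_end"] - tpl["summer_start"] + 1  # inclusive
        assert length == 54

    def test_fewer_than_three_migrants_raises(self):
        ev = self._event(
            date(2019, 6, 12), date(2019, 6, 17),
            date(2019, 8, 30), date(2019, 9, 22),
        )
        with pytest.raises(ValueError, match="manual"):
            resident_seasons([ev, ev])

    def test_january_fall_end_does_not_wrap_the_window(self):
        evs = [
            self._event(
                date(2019, 6, 12), date(2019, 6, 17),
                date(2019, 8, 30), date(2019, 9, 22),
            ),
            self._event(
                date(2019, 6, 10), date(2019, 6, 15),
                date(2019, 9, 5), date(2020, 1, 7),
            ),
            self._event(
                date(2019, 6, 14), date(2019, 6, 20),
                date(2019, 9, 1), date(2019, 10, 1),
            ),
        ]
        tpl = resident_seasons(evs)
        assert tpl["winter_start"] > tpl["summer_end"]

    def test_config_template_matches_published_defaults(self):
        tpl = template_from_config(SeasonTemplate(), 2019)
        assert tpl["summer_start"] == date(2019, 6, 26).timetuple().tm_yday
        assert tpl["winter_start"] == date(2019, 10, 5).timetuple().tm_yday
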