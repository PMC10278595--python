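"""Corridor UDs, route distances, and stopover extraction/merging."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from ovitrack.bbmm_core import RangePolygon
from ovitrack.config import CorridorConfig
from ovitrack.corridors import (
    _merge_near,
    band_corridor,
    corridor_ud,
    extract_stopovers,
    route_distance,
)
from ovitrack.displacement import MigrationEvent, compute_nsd, detect_migration
from ovitrack.synthetic_data import (
    config_for_strategy,
    simulate_band,
    simulate_track,
)
from ovitrack.telemetry_io import clean_track


def event(ss, se, fs=date(2019, 9, 1), fe=date(2019, 9, 13)):
    return MigrationEvent(
        animal_id="T", spring_start=ss, spring_end=se,
        fall_start=fs, fall_end=fe,
    )


class TestRouteDistance:
    def test_three_four_five_closed_form(self, track_factory):
        tr = track_factory(
            [(0, 0), (3, 4), (6, 8)], interval_h=2.0, start="2019-06-12"
        )
        ev = event(date(2019, 6, 12), date(2019, 6, 12))
        assert route_distance(tr, ev, "spring") == pytest.approx(10.0)

    def test_single_fix_window_is_zero(self, track_factory):
        tr = track_factory([(0, 0), (5, 5)], interval_h=48.0,
                           start="2019-06-12")
        ev = event(date(2019, 6, 12), date(2019, 6, 12))
        assert route_distance(tr, ev, "spring") == 0.0

    def test_noise_free_distance_matches_planted_polyline(self):
        """With jitter and observation noise switched off the cumulative
        fix path over the true transit equals the route polyline."""
        cfg = config_for_strategy(
            "LDM", 3,
            loc_error_sd_m=0.0, route_jitter_sd_m=0.0,
            residence_sd_m=0.0, stopover_sd_m=0.0,
        )
        track, gt = simulate_track(cfg)
        # planted route: winter -> dogleg -> summer, 30 km separation
        wc, sc = np.array(gt.winter_centroid), np.array(gt.summer_centroid)
        mid = 0.5 * (wc + sc) + np.array([0.0, cfg.dogleg_m])
        true_km = (
            np.linalg.norm(mid - wc) + np.linalg.norm(sc - mid)
        ) / 1000.0
        ev = event(gt.spring_depart, gt.spring_arrive)
        assert route_distance(track, ev, "spring") == pytest.approx(
            true_km, rel=0.01
        )

    def test_noisy_distance_is_inflated_but_bounded(self):
        """Observation noise and path jitter inflate the cumulative step
        length; the detector's fix-level transit bounds keep the result
        within ~15% of the planted route."""
        cfg = config_for_strategy("LDM", 4)
        track, gt = simulate_track(cfg)
        ev = detect_migration(compute_nsd(track, date(2019, 3, 15)))
        d = route_distance(clean_track(track), ev, "spring")
        wc, sc = np.array(gt.winter_centroid), np.array(gt.summer_centroid)
        mid = 0.5 * (wc + sc) + np.array([0.0, cfg.dogleg_m])
        true_km = (
            np.linalg.norm(mid - wc) + np.linalg.norm(sc - mid)
        ) / 1000.0
        assert 0.9 * true_km < d < 1.3 * true_km


class TestCorridorUD:
    def test_corridor_contains_the_leg(self):
        """The 95% corridor polygon captures at least 99% of the true
        transit positions."""
        cfg = config_for_strategy("LDM", 5)
        track, gt = simulate_track(cfg)
        t = clean_track(track)
        ev = detect_migration(compute_nsd(t, date(2019, 3, 15)))
        c = corridor_ud(t, ev, "spring")
        leg = t.between(gt.spring_depart, gt.spring_arrive)
        inside = c.polygon95.contains_xy(
            leg["x"].to_numpy(), leg["y"].to_numpy()
        )
        assert inside.mean() >= 0.99
        assert c.ud.total_mass() == pytest.approx(1.0, abs=1e-6)

    def test_padding_adds_fixes_around_the_window(self):
        cfg = config_for_strategy("SDM", 6)
        track, _ = simulate_track(cfg)
        t = clean_track(track)
        ev = detect_migration(compute_nsd(t, date(2019, 3, 15)))
        c_padded = corridor_ud(t, ev, "spring")
        unpadded = len(t.between(ev.spring_start, ev.spring_end))
        assert c_padded.ud.n_fixes > unpadded

    def test_too_few_fixes_is_hard_error(self, track_factory):
        tr = track_factory([(0, 0), (1, 1)], interval_h=2.0,
                           start="2019-06-12")
        ev = event(date(2019, 6, 12), date(2019, 6, 12))
        with pytest.raises(ValueError, match="fewer than 4"):
            corridor_ud(tr, ev, "spring")


class TestStopovers:
    @staticmethod
    def _run(seed, strategy="LDM", **overrides):
        cfg = config_for_strategy(strategy, seed, **overrides)
        track, gt = simulate_track(cfg)
        t = clean_track(track)
        ev = detect_migration(compute_nsd(t, date(2019, 3, 15)))
        from ovitrack.ranges import seasonal_range
        from ovitrack.displacement import season_windows_for_migrant

        w = season_windows_for_migrant(t, ev)
        winter = seasonal_range(t, w.winter, "winter")
        summer = seasonal_range(t, w.summer, "summer")
        sites = {}
        for season in ("spring", "fall"):
            c = corridor_ud(t, ev, season)
            sites[season] = extract_stopovers(c, t, [winter, summer])
        return gt, sites

    def test_non_stop_migration_has_no_stopovers(self):
        gt, sites = self._run(
            7, n_stopovers_spring=0, n_stopovers_fall=0
        )
        assert sites["spring"] == [] and sites["fall"] == []

    @pytest.mark.parametrize("seed", [8, 9])
    def test_planted_dwells_recovered_exactly(self, seed):
        gt, sites = self._run(seed)
        assert len(sites["spring"]) == len(gt.stopover_centers_spring) == 1
        assert len(sites["fall"]) == len(gt.stopover_centers_fall) == 2
        # detected sites sit on the planted dwell locations
        for season, centers in (
            ("spring", gt.stopover_centers_spring),
            ("fall", gt.stopover_centers_fall),
        ):
            for s in sites[season]:
                cx, cy = s.centroid
                d = min(
                    np.hypot(cx - px, cy - py) for px, py in centers
                )
                assert d < 500.0

    def test_short_dwell_is_screened_out(self):
        """A 6 h pause fails the 12 h occupancy rule."""
        gt, sites = self._run(
            10, n_stopovers_spring=1, n_stopovers_fall=0,
            stopover_dwell_h=6.0,
        )
        assert sites["spring"] == []

    def test_every_site_meets_occupancy_and_separation_rules(self):
        cfg = CorridorConfig()
        gt, sites = self._run(11)
        flat = sites["spring"] + sites["fall"]
        for s in flat:
            assert sum(s.occupancy.values()) >= cfg.min_occupancy_h
        for season in ("spring", "fall"):
            ss = sites[season]
            for i in range(len(ss)):
                for j in range(i + 1, len(ss)):
                    d = ss[i].as_range().polygon.distance(
                        ss[j].as_range().polygon
                    )
                    assert d >= cfg.merge_distance_m

    def test_band_members_share_stopover_sites(self):
        """Collared migrants of one band use the same stopovers."""
        cfg = config_for_strategy("LDM", 12)
        pairs = simulate_band(2, cfg, spread_m=100.0)
        per_member = []
        for tr, gt in pairs:
            t = clean_track(tr)
            ev = detect_migration(compute_nsd(t, date(2019, 3, 15)))
            from ovitrack.ranges import seasonal_range
            from ovitrack.displacement import season_windows_for_migrant

            w = season_windows_for_migrant(t, ev)
            rngs = [
                seasonal_range(t, w.winter, "winter"),
                seasonal_range(t, w.summer, "summer"),
            ]
            sites = []
            for season in ("spring", "fall"):
                c = corridor_ud(t, ev, season)
                sites.extend(extract_stopovers(c, t, rngs))
            per_member.append(sites)
        a, b = per_member
        assert len(a) == len(b) > 0
        shared = 0
        for s in a:
            ca = np.array(s.centroid)
            if any(
                np.hypot(*(ca - np.array(o.centroid))) < 500.0 for o in b
            ):
                shared += 1
        assert shared / len(a) >= 0.8


class TestMerging:
    def test_merge_boundary_at_300_m(self):
        # single cells: edge gap = (dx - 1) * cell
        a = (frozenset({(0, 0)}), 20.0)
        b_far = (frozenset({(7, 0)}), 20.0)   # 300 m gap: kept apart
        b_near = (frozenset({(6, 0)}), 20.0)  # 250 m gap: merged
        assert len(_merge_near([a, b_far], 50.0, 300.0)) == 2
        merged = _merge_near([a, b_near], 50.0, 300.0)
        assert len(merged) == 1
        assert merged[0][1] == 40.0  # occupancy hours accumulate

    def test_merge_is_order_independent_and_transitive(self):
        comps = [
            (frozenset({(0, 0)}), 1.0),
            (frozenset({(5, 0)}), 2.0),
            (frozenset({(10, 0)}), 4.0),
        ]
        out1 = _merge_near(comps, 50.0, 300.0)
        out2 = _merge_near(comps[::-1], 50.0, 300.0)
        assert out1 == out2
        assert len(out1) == 1  # chained merging reaches a fixed point


class TestBandCorridor:
    def _corridor(self, track):
        t = clean_track(track)
        ev = detect_migration(compute_nsd(t, date(2019, 3, 15)))
        return corridor_ud(t, ev, "spring")

    def test_single_member_is_identity(self):
        track, _ = simulate_track(config_for_strategy("SDM", 13))
        c = self._corridor(track)
        combined = band_corridor([c])
        np.testing.assert_allclose(combined.mass, c.ud.mass)

    def test_two_identical_members_are_idempotent(self):
        track, _ = simulate_track(config_for_strategy("SDM", 13))
        c = self._corridor(track)
        combined = band_corridor([c, c])
        np.testing.assert_allclose(combined.mass, c.ud.mass, atol=1e-12)

    def test_combined_corridor_covers_both_members(self):
        """The band-level 95% polygon captures at least 90% of every
        member's own corridor UD mass."""
        from ovitrack.bbmm_core import isopleth

        cfg = config_for_strategy("SDM", 14)
        pairs = simulate_band(2, cfg, spread_m=100.0)
        cs = [self._corridor(tr) for tr, _ in pairs]
        combined = band_corridor(cs)
        poly = isopleth(combined, 0.95)
        for c in cs:
            g = c.ud.grid
            covered = 0.0
            for (gx, gy) in poly.cells:
                i, j = gx - g.gx0, gy - g.gy0
                if 0 <= i < g.nx and 0 <= j < g.ny:
                    covered += c.ud.mass[j, i]
            assert covered >= 0.90
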