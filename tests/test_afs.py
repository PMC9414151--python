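"""Food-source detection, revisitation curves, buffers and use metrics."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from ravenrange import afs, geo, synth, trackprep
from tests.conftest import FIELD_LAT, FIELD_LON, make_fixes

PROJ = synth.LocalProjection(FIELD_LON, FIELD_LAT)


def fixes_at_xy(xy, times, individual="B001"):
    xy = np.asarray(xy, float)
    lon, lat = PROJ.inverse(xy[:, 0], xy[:, 1])
    return make_fixes(times, lon, lat, individual)


def minutes_after(start, mins):
    return [start + dt.timedelta(minutes=m) for m in mins]


T0 = dt.datetime(2018, 7, 1, 8)


class TestDetectClusters:
    def test_nine_fixes_are_below_threshold(self):
        xy = np.random.default_rng(0).normal(0, 50, (9, 2))
        fixes = fixes_at_xy(xy, minutes_after(T0, range(0, 180, 20)))
        assert afs.detect_clusters(fixes) == []

    def test_ten_colocated_fixes_make_one_site_at_centroid(self):
        xy = np.zeros((10, 2))
        fixes = fixes_at_xy(xy, minutes_after(T0, range(0, 200, 20)))
        sites = afs.detect_clusters(fixes)
        assert len(sites) == 1
        d = float(geo.haversine_m(sites[0].lon, sites[0].lat, FIELD_LON, FIELD_LAT))
        assert d < 1.0

    def test_empty_input_gives_empty_result(self):
        empty = make_fixes([], [], [])
        assert afs.detect_clusters(empty) == []

    def test_planted_sites_recovered_exactly(self, planted_sites_fixture):
        fixes, centres = planted_sites_fixture
        sites = afs.detect_clusters(fixes)
        assert len(sites) == len(centres)
        # each true centre matched within 50 m by exactly one detection
        for clon, clat in centres:
            d = [float(geo.haversine_m(s.lon, s.lat, clon, clat)) for s in sites]
            assert min(d) < 50.0

    def test_planted_sites_agree_with_neighbourhood_counting_oracle(self, planted_sites_fixture):
        fixes, centres = planted_sites_fixture
        sites = afs.detect_clusters(fixes, min_count=10, radius=200.0)
        # brute force: a point is a core point iff >= 10 fixes within 200 m
        lon = fixes["lon"].to_numpy()
        lat = fixes["lat"].to_numpy()
        n = len(lon)
        core = np.zeros(n, bool)
        for i in range(n):
            d = geo.haversine_m(lon[i], lat[i], lon, lat)
            core[i] = (d <= 200.0).sum() >= 10
        # every detected site centre must sit within 200 m of a core point
        for s in sites:
            d = geo.haversine_m(s.lon, s.lat, lon[core], lat[core])
            assert d.min() <= 200.0
        # and every core point must belong to some detected site's cluster
        for i in np.flatnonzero(core):
            d = [float(geo.haversine_m(lon[i], lat[i], s.lon, s.lat)) for s in sites]
            assert min(d) < 400.0


class TestRevisitationCurve:
    def site(self):
        return afs.AfsSite(site_id="S1", lon=FIELD_LON, lat=FIELD_LAT)

    def test_single_pass_is_one_visit_at_every_radius(self):
        # straight transit through the circle
        xy = [(x, 0.0) for x in range(-400, 401, 50)]
        fixes = fixes_at_xy(xy, minutes_after(T0, range(0, 17 * 5, 5)))
        curve = afs.revisitation_curve(fixes, self.site(), radii=[50, 100, 150])
        assert list(curve.revisits) == [1, 1, 1]

    def test_three_entries_merge_as_radius_grows(self):
        # in/out of the 50 m circle three times, excursions stay inside 150 m
        path = [
            (0, 0), (100, 0),  # out to 100 m
            (0, 0), (100, 0),  # and again
            (0, 0),
        ]
        fixes = fixes_at_xy(path, minutes_after(T0, range(0, 25, 5)))
        curve = afs.revisitation_curve(fixes, self.site(), radii=[50, 150])
        assert curve.revisits[0] == 3
        assert curve.revisits[1] == 1

    def test_coverage_monotone_and_revisits_match_rle_oracle(self):
        rng = np.random.default_rng(7)
        xy = np.cumsum(rng.normal(0, 60, (300, 2)), axis=0)
        fixes = fixes_at_xy(xy, minutes_after(T0, range(0, 1500, 5)))
        radii = list(range(20, 151, 10))
        curve = afs.revisitation_curve(fixes, self.site(), radii=radii)
        assert np.all(np.diff(curve.coverage) >= 0)
        d = geo.haversine_m(fixes["lon"].to_numpy(), fixes["lat"].to_numpy(), FIELD_LON, FIELD_LAT)
        for k, r in enumerate(radii):
            inside = d <= r
            runs = int(np.sum(inside[1:] & ~inside[:-1]) + inside[0])
            assert curve.revisits[k] == runs
            assert curve.coverage[k] == inside.sum()
            if curve.coverage[k] >= 1:
                assert curve.revisits[k] >= 1

    def test_gap_longer_than_five_hours_splits_a_visit(self):
        times = [T0, T0 + dt.timedelta(minutes=10), T0 + dt.timedelta(hours=7)]
        fixes = fixes_at_xy([(0, 0)] * 3, times)
        curve = afs.revisitation_curve(fixes, self.site(), radii=[50])
        assert curve.revisits[0] == 2

    def test_site_outside_data_is_a_zero_curve(self):
        far = afs.AfsSite(site_id="S9", lon=FIELD_LON + 1.0, lat=FIELD_LAT)
        fixes = fixes_at_xy([(0, 0)] * 5, minutes_after(T0, range(0, 100, 20)))
        curve = afs.revisitation_curve(fixes, far, radii=[50, 150])
        assert curve.revisits.sum() == 0 and curve.coverage.sum() == 0


class TestSelectBuffer:
    def test_exact_plateau(self):
        curve = afs.RevisitationCurve("S1", [20, 50, 80, 100, 150], [2, 6, 9, 9, 9], [5, 9, 20, 20, 20])
        assert afs.select_buffer(curve) == 80.0

    def test_strictly_increasing_curve_hits_the_cap(self):
        curve = afs.RevisitationCurve("S1", [20, 50, 80, 100, 150], [2, 4, 8, 12, 16], [2, 4, 8, 12, 16])
        assert afs.select_buffer(curve) == 150.0

    def test_all_zero_curve_flags_unused_site(self):
        curve = afs.RevisitationCurve("S1", [20, 50], [0, 0], [0, 0])
        assert afs.select_buffer(curve) is None

    def test_noisy_simulated_curves_recover_generating_dwell_radius(self):
        # densely sampled passes whose closest approaches are spread over a
        # known dwell radius: revisits climb until that radius, then
        # plateau, so the chosen buffer should land within one 10-m grid
        # step of the dwell radius in most replicates
        rng = np.random.default_rng(21)
        hits = 0
        reps = 50
        dwell_radius = 80.0
        radii = list(range(20, 151, 10))
        for _ in range(reps):
            rows = []
            t = T0
            for _visit in range(16):
                depth = dwell_radius * rng.random()  # closest approach
                th = rng.uniform(0, 2 * np.pi)
                ux, uy = np.cos(th), np.sin(th)
                for dist in list(range(300, int(depth), -20)) + [depth] + list(range(int(depth) + 20, 301, 20)):
                    rows.append((t, dist * ux + depth * -uy * 0.0, dist * uy))
                    t += dt.timedelta(minutes=2)
                rows.append((t, 5000.0, 5000.0))
                t += dt.timedelta(minutes=40)
            fixes = fixes_at_xy([(x, y) for _, x, y in rows], [r[0] for r in rows])
            curve = afs.revisitation_curve(fixes, afs.AfsSite("S1", FIELD_LON, FIELD_LAT), radii)
            chosen = afs.select_buffer(curve)
            if chosen is not None and abs(chosen - dwell_radius) <= 10.0:
                hits += 1
        assert hits >= 0.8 * reps


def _segment(fixes):
    return trackprep.SeasonYearSegment(
        individual_id=str(fixes["individual_id"].iloc[0]), season="summer",
        year_label=2018, fixes=fixes, age_class="adult",
    )


def _sites_at(centres_xy, radius=100.0):
    out = []
    for k, (x, y) in enumerate(centres_xy):
        lon, lat = PROJ.inverse(x, y)
        out.append(afs.AfsSite(f"S{k}", float(lon), float(lat), buffer_radius=radius))
    return out


class TestUseMetrics:
    def test_no_fixes_in_any_buffer(self):
        seg = _segment(fixes_at_xy([(5000, 5000)] * 4, minutes_after(T0, range(0, 80, 20))))
        sites = _sites_at([(0, 0), (1000, 0)])
        assert afs.count_afs_visited(seg, sites) == 0
        assert afs.prop_in_any_buffer(seg, sites) is None  # excluded, not zero

    def test_three_buffers_visited_repeatedly_counts_three(self):
        path = [(0, 0), (1000, 0), (2000, 0)] * 3
        seg = _segment(fixes_at_xy(path, minutes_after(T0, range(0, 9 * 20, 20))))
        sites = _sites_at([(0, 0), (1000, 0), (2000, 0)])
        assert afs.count_afs_visited(seg, sites) == 3

    def test_simple_proportions(self):
        path = [(0, 0)] * 5 + [(9000, 9000)] * 15
        seg = _segment(fixes_at_xy(path, minutes_after(T0, range(0, 400, 20))))
        sites = _sites_at([(0, 0)])
        assert afs.prop_in_any_buffer(seg, sites) == pytest.approx(0.25)
        assert afs.max_single_site_prop(seg, sites) == pytest.approx(0.25)

    def test_two_disjoint_sites_max_single_prop(self):
        path = [(0, 0)] * 3 + [(5000, 0)] * 1 + [(9000, 9000)] * 6
        seg = _segment(fixes_at_xy(path, minutes_after(T0, range(0, 200, 20))))
        sites = _sites_at([(0, 0), (5000, 0)])
        assert afs.prop_in_any_buffer(seg, sites) == pytest.approx(0.4)
        assert afs.max_single_site_prop(seg, sites) == pytest.approx(0.3)

    def test_overlapping_buffers_union_matches_inclusion_exclusion(self):
        rng = np.random.default_rng(5)
        xy = rng.uniform(-300, 300, (200, 2))
        seg = _segment(fixes_at_xy(xy, minutes_after(T0, range(0, 4000, 20))))
        sites = _sites_at([(0, 0), (120, 0)], radius=150.0)
        lon = seg.fixes["lon"].to_numpy()
        lat = seg.fixes["lat"].to_numpy()
        in_a = geo.haversine_m(lon, lat, sites[0].lon, sites[0].lat) <= 150.0
        in_b = geo.haversine_m(lon, lat, sites[1].lon, sites[1].lat) <= 150.0
        union = in_a.sum() + in_b.sum() - (in_a & in_b).sum()
        assert afs.prop_in_any_buffer(seg, sites) == pytest.approx(union / len(lon))
        # a fix inside both buffers counts toward both sites
        assert afs.count_afs_visited(seg, sites) == int(in_a.any()) + int(in_b.any())

    def test_exhaustive_point_in_circle_oracle(self):
        rng = np.random.default_rng(8)
        xy = rng.uniform(-4000, 4000, (150, 2))
        seg = _segment(fixes_at_xy(xy, minutes_after(T0, range(0, 3000, 20))))
        centres = [(-2000, -2000), (0, 0), (2500, 1000)]
        sites = _sites_at(centres, radius=120.0)
        lon = seg.fixes["lon"].to_numpy()
        lat = seg.fixes["lat"].to_numpy()
        inside = np.zeros((len(lon), len(sites)), bool)
        for j, s in enumerate(sites):
            inside[:, j] = geo.haversine_m(lon, lat, s.lon, s.lat) <= 120.0
        assert afs.count_afs_visited(seg, sites) == inside.any(axis=0).sum()
        assert afs.max_single_site_prop(seg, sites) == pytest.approx(inside.mean(axis=0).max())

    def test_growing_buffers_never_shrink_use_metrics(self):
        rng = np.random.default_rng(9)
        xy = rng.uniform(-2000, 2000, (120, 2))
        seg = _segment(fixes_at_xy(xy, minutes_after(T0, range(0, 2400, 20))))
        centres = [(-900, 0), (700, 400)]
        small = _sites_at(centres, radius=60.0)
        big = _sites_at(centres, radius=140.0)
        assert afs.count_afs_visited(seg, big) >= afs.count_afs_visited(seg, small)
        p_small = afs.prop_in_any_buffer(seg, small) or 0.0
        p_big = afs.prop_in_any_buffer(seg, big) or 0.0
        assert p_big >= p_small


class TestExports:
    def test_buffers_geojson_circles_have_requested_radius(self):
        sites = _sites_at([(0, 0)], radius=100.0)
        fc = afs.buffers_geojson(sites)
        (feat,) = fc["features"]
        ring = np.array(feat["geometry"]["coordinates"][0])
        d = geo.haversine_m(ring[:, 0], ring[:, 1], sites[0].lon, sites[0].lat)
        np.testing.assert_allclose(d, 100.0, rtol=1e-6)

    def test_curves_table_is_tidy(self):
        c = afs.RevisitationCurve("S1", [20, 50], [1, 2], [3, 4])
        t = afs.curves_table([c])
        assert list(t.columns) == ["site_id", "radius_m", "revisits", "coverage"]
        assert len(t) == 2


class TestEndToEndPlantedFixture:
    def test_detection_buffers_and_visits_reproduce_ground_truth(self, planted_sites_fixture):
        fixes, centres = planted_sites_fixture
        sub = trackprep.subsample_min_interval(fixes)
        sites = afs.detect_clusters(sub)
        assert len(sites) == len(centres)
        afs.calibrate_buffers(fixes, sites)
        assert all(s.buffer_radius is not None for s in sites)
        seg = _segment(fixes)
        # ground truth: the one bird visits each planted site exactly once,
        # so it intersects all five buffers
        assert afs.count_afs_visited(seg, sites) == 5
        # per-site visit counts at the calibrated buffer match a brute-force
        # run-length encoding of the inside indicator
        for s in sites:
            d = geo.haversine_m(fixes["lon"].to_numpy(), fixes["lat"].to_numpy(), s.lon, s.lat)
            inside = d <= s.buffer_radius
            runs = int(np.sum(inside[1:] & ~inside[:-1]) + inside[0])
            curve = afs.revisitation_curve(fixes, s, radii=[s.buffer_radius])
            assert curve.revisits[0] == runs
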