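"""Speed/behaviour labelling, trip segmentation and distance machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon

from aukforage import synthetic_data as sd
from aukforage import tracks
from aukforage.geo import EARTH_RADIUS_KM, LocalProjection, haversine_km


def _fixes(points, t0="2012-07-20", dt_h=1.0, bird="b1"):
    times = pd.Timestamp(t0) + pd.to_timedelta(np.arange(len(points)) * dt_h, unit="h")
    lon, lat = zip(*points)
    return pd.DataFrame({"bird_id": bird, "t": times, "lon": lon, "lat": lat})


def _reference_haversine(lon1, lat1, lon2, lat2):
    """Independent spherical-law-of-cosines distance (R = 6371 km)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(lon2 - lon1)
    cos_c = np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl)
    return EARTH_RADIUS_KM * np.arccos(np.clip(cos_c, -1, 1))


class TestComputeSpeeds:
    def test_threshold_is_strict_at_10kmh(self):
        # 10 km in 1 h due north: speed ~10 km/h; relabelling with the
        # threshold set to the computed speed itself must give travel
        # (strict <) while any higher threshold gives forage_rest
        lat2 = 10.0 / (EARTH_RADIUS_KM * np.pi / 180.0)
        f = _fixes([(0, 0), (0, lat2)])
        out = tracks.compute_speeds(f)
        v = float(out.speed_kmh.iloc[1])
        assert v == pytest.approx(10.0, rel=1e-6)
        at = tracks.compute_speeds(f, threshold_kmh=v)
        above = tracks.compute_speeds(f, threshold_kmh=np.nextafter(v, np.inf))
        assert at.behaviour.iloc[1] == tracks.TRAVEL
        assert above.behaviour.iloc[1] == tracks.FORAGE_REST

    def test_coincident_fixes_are_forage_rest(self):
        out = tracks.compute_speeds(_fixes([(5, 60), (5, 60)]))
        assert out.speed_kmh.iloc[1] == 0.0
        assert out.behaviour.iloc[1] == tracks.FORAGE_REST

    def test_colony_segment_speed_matches_haversine_oracle(self):
        d = _reference_haversine(-21.583, 70.733, -21.0, 70.733)
        out = tracks.compute_speeds(
            _fixes([(-21.583, 70.733), (-21.0, 70.733)], dt_h=0.5))
        assert d == pytest.approx(21.39, abs=0.05)  # frozen from the oracle
        assert out.speed_kmh.iloc[1] == pytest.approx(d / 0.5, rel=1e-6)
        assert out.speed_kmh.iloc[1] == pytest.approx(42.8, abs=0.1)

    def test_first_fix_unlabelled_partition_invariant(self, cfg):
        fixes, _ = sd.gen_tracks(cfg)
        out = tracks.compute_speeds(fixes)
        n_tracks = fixes.bird_id.nunique()
        labelled = out.behaviour.notna().sum()
        assert labelled == len(out) - n_tracks
        assert out.groupby("bird_id").speed_kmh.apply(
            lambda s: np.isnan(s.iloc[0])).all()

    def test_duplicate_timestamp_names_bird_and_time(self):
        f = _fixes([(0, 0), (0, 1), (0, 2)])
        f.loc[2, "t"] = f.loc[1, "t"]
        with pytest.raises(ValueError, match="b1"):
            tracks.compute_speeds(f)

    def test_single_fix_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            out = tracks.compute_speeds(_fixes([(0, 0)]))
        assert out.empty

    def test_gap_segments_excluded_from_labelling(self):
        f = _fixes([(0, 0), (0, 0.01), (0, 0.02), (0, 0.03)])
        f.loc[3, "t"] += pd.Timedelta(hours=10)
        out = tracks.compute_speeds(f)
        assert bool(out.gap.iloc[3])
        assert pd.isna(out.behaviour.iloc[3])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(
        st.floats(-179, 179), st.floats(-80, 80),
        st.floats(-179, 179), st.floats(-80, 80)))
    def test_haversine_agrees_with_independent_oracle(self, quad):
        lon1, lat1, lon2, lat2 = quad
        ours = haversine_km(lon1, lat1, lon2, lat2)
        ref = _reference_haversine(lon1, lat1, lon2, lat2)
        assert ours == pytest.approx(ref, rel=1e-3, abs=1e-4)


class TestSegmentTrips:
    def test_out_and_back_recovers_apex(self, cfg):
        fixes, truth = sd.gen_tracks(cfg)
        trips = tracks.segment_trips(fixes, cfg.colony)
        assert len(trips) == len(truth)
        for tr in trips:
            apex = truth.set_index("bird_id").apex_km[tr.bird_id]
            assert tr.complete
            assert tr.max_distance_km == pytest.approx(apex, rel=1e-3)
            assert tr.path_length_km >= tr.max_distance_km

    def test_track_ending_at_sea_is_incomplete(self, cfg):
        fixes, _ = sd.gen_tracks(cfg, n_birds=1)
        truncated = fixes.iloc[:-5]
        trips = tracks.segment_trips(truncated, cfg.colony)
        assert len(trips) == 1 and not trips[0].complete
        summ = tracks.trip_summary(trips)
        assert np.isnan(summ["table"].duration_h.iloc[0])

    def test_all_fixes_at_colony_yield_no_trips(self, cfg):
        f = _fixes([cfg.colony] * 4)
        assert tracks.segment_trips(f, cfg.colony) == []

    def test_path_length_bounds_displacement(self, cfg):
        fixes, _ = sd.gen_tracks(cfg)
        for tr in tracks.segment_trips(fixes, cfg.colony):
            first, last = tr.fixes.iloc[0], tr.fixes.iloc[-1]
            disp = haversine_km(first.lon, first.lat, last.lon, last.lat)
            assert tr.path_length_km >= disp - 1e-9


class TestRankSum:
    def test_identical_groups_p_one(self):
        res = tracks.rank_sum_test([1, 2, 3], [1, 2, 3])
        assert res["p"] == pytest.approx(1.0)

    def test_separated_groups_match_enumeration(self):
        # all 20 assignments of {1..6} into two triples: P(U <= 0) = 1/20 each tail
        res = tracks.rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res["W"] == 0.0
        assert res["method"] == "exact"
        assert res["p"] == pytest.approx(0.1)

    def test_type_i_error_near_alpha(self):
        rng = np.random.default_rng(42)
        rejections = sum(
            tracks.rank_sum_test(rng.normal(size=8), rng.normal(size=8))["p"] < 0.05
            for _ in range(1000))
        assert 30 <= rejections <= 70  # ~0.05 +- 2 binomial SDs

    def test_summary_skips_test_for_empty_group(self, cfg):
        fixes, _ = sd.gen_tracks(cfg, year=2012)
        trips = tracks.segment_trips(fixes, cfg.colony)
        with pytest.warns(UserWarning):
            out = tracks.trip_summary(trips, compare=(2012, 2014))
        assert out["tests"] == {}


class TestDistanceToPolygon:
    def test_point_on_vertex_is_zero(self, cfg):
        proj = cfg.projection()
        poly = sd.gen_ice_polygon(cfg, edge_distance_km=23.0)
        lon, lat = poly.exterior.coords[0]
        d = tracks.distance_to_polygon([lon], [lat], poly, proj)
        assert d[0] == pytest.approx(0.0, abs=0.5)

    def test_point_100km_south_of_edge(self):
        proj = LocalProjection(0.0, 70.0)
        # east-west edge along y=0 in the local frame
        corners = [proj.inverse(x, y) for x, y in
                   [(-200, 0), (200, 0), (200, 300), (-200, 300)]]
        poly = Polygon([(float(a), float(b)) for a, b in corners])
        lon, lat = (float(v) for v in proj.inverse(0.0, -100.0))
        d = tracks.distance_to_polygon([lon], [lat], poly, proj)
        assert d[0] == pytest.approx(100.0, abs=0.5)

    def test_empty_polygon_raises(self, cfg):
        with pytest.raises(ValueError):
            tracks.distance_to_polygon([0], [70], Polygon(), cfg.projection())

    def test_median_ice_distance_recovers_placement(self):
        cfg = sd.ScenarioConfig(seed=3, n_birds=20)
        proj = cfg.projection()
        fixes, _ = sd.gen_tracks(cfg)
        lab = tracks.compute_speeds(fixes)
        forage = lab[lab.behaviour == tracks.FORAGE_REST]
        for placed in (23.0, 152.0):
            ice = sd.gen_ice_polygon(cfg, edge_distance_km=placed)
            d = tracks.distance_to_polygon(forage.lon, forage.lat, ice, proj)
            assert np.median(d) == pytest.approx(placed, abs=0.25 * placed + 5)
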