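"""Readers, event→polygon assignment, contiguity and metric distances."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Point, Polygon, box

import crimescape as cs
from crimescape.errors import FormatError
from crimescape.geoio import EARTH_RADIUS_KM, KM_PER_DEG

from conftest import SEED


# ---------------------------------------------------------------------------
# event CSV reading
# ---------------------------------------------------------------------------

class TestReadEvents:
    def test_well_formed_rows_all_accepted(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text("date,lat,lon,casualties\n"
                     "2011-01-05,25.7,-100.3,1\n"
                     "2011-02-01,25.71,-100.31,2\n"
                     "2011-03-01,25.72,-100.32,1\n")
        df = cs.read_events(p)
        assert len(df) == 3
        assert df.attrs["rejected"] == []
        assert df["casualties"].tolist() == [1, 2, 1]

    def test_malformed_rows_rejected_with_row_numbers(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text("date,lat,lon,casualties\n"
                     "2011-01-05,25.7,-100.3,1\n"
                     "2011-02-01,,-100.31,2\n"
                     "not-a-date,25.7,-100.3,1\n")
        df = cs.read_events(p)
        assert len(df) == 1
        assert [r for r, _ in df.attrs["rejected"]] == [2, 3]

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text("date,lat,casualties\n2011-01-05,25.7,1\n")
        with pytest.raises(FormatError):
            cs.read_events(p)

    def test_synthetic_roundtrip(self, tmp_path):
        cfg = cs.CityConfig(base_rate=0.15, n_weeks=40, seed=SEED)
        ev = cs.generate_events(cs.generate_city(cfg), cfg)
        p = tmp_path / "ev.csv"
        cs.write_events(ev, p)
        back = cs.read_events(p)
        assert len(back) == len(ev)
        assert back.attrs["rejected"] == []
        np.testing.assert_allclose(back["lat"], ev["lat"].to_numpy())
        np.testing.assert_allclose(back["lon"], ev["lon"].to_numpy())
        assert (back["date"].to_numpy()
                == pd.to_datetime(ev["date"]).dt.normalize().to_numpy()).all()


# ---------------------------------------------------------------------------
# event → neighborhood mapping
# ---------------------------------------------------------------------------

class TestMapEvents:
    def test_centroid_point_assigned_to_its_cell(self, grid10):
        _, nmap, _, _ = grid10
        n = nmap[nmap.ids[37]]
        df = pd.DataFrame({"date": [pd.Timestamp("2011-01-05")],
                           "lat": [n.centroid[1]], "lon": [n.centroid[0]],
                           "casualties": [1]})
        mapped, dropped = cs.map_events(df, nmap)
        assert dropped == 0
        assert mapped["neighborhood_id"].iloc[0] == n.id

    def test_outside_point_dropped(self, grid10):
        _, nmap, _, _ = grid10
        df = pd.DataFrame({"date": [pd.Timestamp("2011-01-05")],
                           "lat": [0.0], "lon": [0.0], "casualties": [1]})
        mapped, dropped = cs.map_events(df, nmap)
        assert len(mapped) == 0 and dropped == 1

    def test_idempotent(self, busy_city):
        _, (nmap, _, _), mapped, _ = busy_city
        again, dropped = cs.map_events(mapped, nmap)
        assert dropped == 0
        pd.testing.assert_frame_equal(again, mapped.reset_index(drop=True))

    def test_generated_events_map_back_to_their_cell(self, busy_city):
        cfg, (nmap, _, _), mapped, dropped = busy_city
        assert dropped == 0
        ev = cs.generate_events(cs.generate_city(cfg), cfg)
        assert (mapped["neighborhood_id"].to_numpy()
                == ev["neighborhood_id"].to_numpy()).all()

    def test_empty_map_rejected(self, busy_city):
        with pytest.raises(ValueError):
            cs.map_events(busy_city[2], None)


def ray_cast_inside(poly_coords, x, y):
    """Independent even-odd ray-casting point-in-polygon test."""
    inside = False
    n = len(poly_coords)
    for i in range(n - 1):
        x1, y1 = poly_coords[i]
        x2, y2 = poly_coords[i + 1]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


def test_assignment_matches_ray_casting_oracle(grid10):
    _, nmap, _, _ = grid10
    rng = np.random.default_rng(SEED)
    lon_min, lat_min, lon_max, lat_max = nmap.bounds()
    # pad so some points fall outside the tessellation
    lon = rng.uniform(lon_min - 0.01, lon_max + 0.01, 300)
    lat = rng.uniform(lat_min - 0.01, lat_max + 0.01, 300)
    assigned = nmap.assign_points(lon, lat)
    rings = {n.id: list(n.polygon.exterior.coords) for n in nmap}
    for x, y, got in zip(lon, lat, assigned):
        oracle = sorted(nid for nid, ring in rings.items()
                        if ray_cast_inside(ring, x, y))
        if not oracle and any(nmap[nid].polygon.boundary.distance(Point(x, y))
                              < 1e-12 for nid in nmap.ids):
            continue  # boundary points: tie-break rule applies, oracle silent
        assert got == (oracle[0] if oracle else None)


# ---------------------------------------------------------------------------
# contiguity
# ---------------------------------------------------------------------------

class TestAdjacency:
    def test_2x2_grid_queen_has_6_pairs(self):
        cfg = cs.CityConfig(n_rows=2, n_cols=2, n_municipalities=1,
                            populations=[1e5], seed=SEED)
        nmap, _, _ = cs.generate_city(cfg)
        assert len(cs.adjacency(nmap, "queen")) == 6
        assert len(cs.adjacency(nmap, "rook")) == 4

    def test_3x3_center_touches_all_8(self):
        cfg = cs.CityConfig(n_rows=3, n_cols=3, n_municipalities=1,
                            populations=[1e5], seed=SEED)
        nmap, _, _ = cs.generate_city(cfg)
        center = cs.cell_id(cfg, 4)
        adj = cs.adjacency(nmap, "queen")
        deg = sum(1 for a, b in adj if center in (a, b))
        assert deg == 8

    def test_disjoint_squares_not_adjacent(self):
        a = box(-100.3, 25.7, -100.29, 25.71)
        b = box(-100.27, 25.7, -100.26, 25.71)  # ~1 km east
        nmap = cs.NeighborhoodMap.from_polygons(
            [("a", "M", a), ("b", "M", b)])
        assert cs.adjacency(nmap) == set()

    def test_grid_adjacency_matches_index_arithmetic(self, grid10):
        cfg, nmap, _, _ = grid10
        expected = set()
        for k in range(100):
            r, c = divmod(k, 10)
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < 10 and 0 <= cc < 10:
                        j = rr * 10 + cc
                        expected.add(tuple(sorted((cs.cell_id(cfg, k),
                                                   cs.cell_id(cfg, j)))))
        assert cs.adjacency(nmap, "queen") == expected


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

class TestDistances:
    def test_same_neighborhood_zero(self, grid10):
        _, nmap, _, _ = grid10
        n = nmap[nmap.ids[0]]
        assert cs.centroid_distance_km(n, n) == 0.0

    def test_one_degree_latitude(self):
        # closed form: R * pi/180
        d = cs.haversine_km(-100.3, 25.0, -100.3, 26.0)
        assert d == pytest.approx(EARTH_RADIUS_KM * math.pi / 180.0, rel=1e-12)
        assert d == pytest.approx(111.2, abs=0.05)

    def test_triangle_inequality_on_5x5_grid(self):
        cfg = cs.CityConfig(n_rows=5, n_cols=5, n_municipalities=1,
                            populations=[1e5], seed=SEED)
        nmap, _, _ = cs.generate_city(cfg)
        ns = list(nmap)
        d = {(a.id, b.id): cs.centroid_distance_km(a, b)
             for a in ns for b in ns}
        for a in ns:
            for b in ns:
                for c in ns:
                    assert (d[a.id, b.id] + d[b.id, c.id]
                            >= d[a.id, c.id] - 1e-9)

    @given(st.floats(-100.8, -99.6), st.floats(25.3, 26.0),
           st.floats(-100.8, -99.6), st.floats(25.3, 26.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_haversine_symmetric_nonnegative(self, lon1, lat1, lon2, lat2):
        d = cs.haversine_km(lon1, lat1, lon2, lat2)
        assert d >= 0
        assert d == pytest.approx(cs.haversine_km(lon2, lat2, lon1, lat1))

    def test_pairwise_matches_elementwise(self, grid10):
        _, nmap, _, _ = grid10
        pairs, dists = cs.pairwise_centroid_distances(nmap)
        for (a, b), d in list(zip(pairs, dists))[::97]:
            assert d == pytest.approx(
                cs.centroid_distance_km(nmap[a], nmap[b]), rel=1e-12)


# ---------------------------------------------------------------------------
# GeoJSON / OSM round trips
# ---------------------------------------------------------------------------

class TestGeoJsonIO:
    def test_neighborhood_roundtrip(self, grid10, tmp_path):
        _, nmap, _, _ = grid10
        p = tmp_path / "n.geojson"
        nmap.to_geojson(p)
        back = cs.NeighborhoodMap.from_geojson(p)
        assert back.ids == nmap.ids
        assert back.areas_km2().to_numpy() == pytest.approx(
            nmap.areas_km2().to_numpy(), rel=1e-9)

    def test_highway_roundtrip(self, grid10, tmp_path):
        _, _, _, hw = grid10
        p = tmp_path / "h.geojson"
        hw.to_geojson(p)
        back = cs.HighwaySet.from_geojson(p)
        assert len(back) == len(hw)
        np.testing.assert_allclose(np.asarray(back.polylines[0]),
                                   np.asarray(hw.polylines[0]))

    def test_osm_xml_reader_filters_tags_and_bbox(self, tmp_path):
        xml = """<?xml version='1.0'?>
        <osm>
          <node id='1' lon='-100.30' lat='25.70'/>
          <node id='2' lon='-100.29' lat='25.71'/>
          <node id='3' lon='-100.28' lat='25.72'/>
          <node id='4' lon='-120.0' lat='40.0'/>
          <way id='10'><nd ref='1'/><nd ref='2'/><nd ref='3'/>
            <tag k='highway' v='motorway'/></way>
          <way id='11'><nd ref='1'/><nd ref='2'/>
            <tag k='highway' v='residential'/></way>
          <way id='12'><nd ref='1'/><nd ref='4'/>
            <tag k='highway' v='trunk'/></way>
        </osm>"""
        p = tmp_path / "h.osm"
        p.write_text(xml)
        hw = cs.HighwaySet.from_osm_xml(p)
        # residential filtered out; way 12 loses its out-of-bbox node
        assert len(hw) == 1
        assert hw.way_ids == ["10"]
        assert len(hw.polylines[0]) == 3
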